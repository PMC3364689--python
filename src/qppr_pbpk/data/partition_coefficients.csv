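# Rat blood:air and human tissue:blood partition coefficients for 37 volatile
# organic chemicals, compiled from published in-vitro vial-equilibration
# measurements. p_pl_blood is the phospholipid:blood partition coefficient
# derived from octanol:air, water:air and blood:air partitioning.
# Values at the precision of the published compilation.
name,dataset,pba,p_liver_blood,p_rich_blood,p_poor_blood,p_fat_blood,p_pl_blood
benzene,calibration,8.19,2.08,2.08,1.26,60.93,4.55
bromochloromethane,calibration,10.4,2.81,2.81,1.07,31.5,2
bromodichloromethane,calibration,26.6,1.15,1.15,0.47,19.77,2.48
carbon tetrachloride,calibration,2.73,5.2,5.2,1.67,131.5,8.57
chloroethane,calibration,2.69,1.34,1.34,1.2,14.3,4.42
chloroform,calibration,6.85,3.08,3.08,2.03,29.6,1.93
dibromomethane,calibration,19.9,3.42,3.42,2.03,39.8,1.78
"1,1-dichloroethane",calibration,4.94,2.19,2.19,1.04,33.2,4.27
"1,2-dichloroethane",calibration,19.5,1.83,1.83,1.2,17.64,9.25
"1,1-dichloroethylene",calibration,0.81,5.46,5.46,2.53,84.69,4.82
"cis-1,2-dichloroethylene",calibration,9.85,1.55,1.55,0.62,23,5.2
dichloromethane,calibration,9.7,1.46,1.46,0.82,12.4,1.79
ethylbenzene,calibration,28,2.99,2.15,0.93,55.6,13.2
hexachloroethane,calibration,52.4,7.04,7.04,1.43,63.4,156
n-hexane,calibration,2.13,5.2,5.2,2.9,159,1.89
isoprene,calibration,0.75,2.57,2.45,1.97,82,11.84
methyl chloride,calibration,2.48,1.4,1.4,0.39,5.44,3.04
pentachloroethane,calibration,50.3,5.17,5.17,1.44,81.9,21.7
styrene,calibration,52,2.7,5.7,1,50,30.2
"1,1,1,2-tetrachloroethane",calibration,30.2,2.92,2.92,1.31,71.1,37.3
"1,1,2,2-tetrachloroethane",calibration,116,1.69,1.69,0.87,32.47,14.3
toluene,calibration,15.6,5.36,5.36,1.77,65.4,13.8
"1,1,2-trichloroethane",calibration,35.7,2.05,2.05,0.64,40.3,10.1
trichloroethylene,calibration,8.11,3.35,3.35,1.24,68.3,5.73
vinyl chloride,calibration,1.16,1.38,1.38,1.81,17.2,4.87
m-xylene,calibration,26.4,3.44,3.44,1.59,70.4,15.1
bromoform,evaluation,102.3,2.06,2.06,1.12,40.4,2.44
dibromochloromethane,evaluation,49.2,2.56,2.56,1.13,38.96,1.48
"trans-1,2-dichloroethylene",evaluation,6.04,1.48,1.48,0.58,24.5,11.7
ethylene,evaluation,0.22,2.05,2.18,2.95,8.73,1.05
furan,evaluation,6.59,0.9,0.9,0.64,9.72,2.75
halothane,evaluation,3.3,2.42,2.42,2.91,44.2,5.82
propylene,evaluation,0.44,1.09,1.2,1.25,11.7,1.52
tetrachloroethylene,evaluation,10.3,5.88,5.88,3.1,119.1,11.1
"1,1,1-trichloroethane",evaluation,2.53,1.24,3.4,3.4,103.9,21.7
"1,2,4-trimethylbenzene",evaluation,85,4.4,4.4,2.11,109,19
o-xylene,evaluation,34.9,3.09,3.09,1.47,53.8,22.6
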
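# Molecular weights (standard chemistry values, not part of the compiled
# experimental dataset) and first-order hepatic metabolic constants kf (1/h;
# nonzero only for the four chemicals whose in-vivo clearance includes a
# first-order component).
name,mw,kf
benzene,78.11,0
bromochloromethane,129.38,0
bromodichloromethane,163.83,0
carbon tetrachloride,153.82,0
chloroethane,64.51,1
chloroform,119.38,0
dibromomethane,173.83,0.7
"1,1-dichloroethane",98.96,0
"1,2-dichloroethane",98.96,0
"1,1-dichloroethylene",96.94,0
"cis-1,2-dichloroethylene",96.94,0
dichloromethane,84.93,2
ethylbenzene,106.17,0
hexachloroethane,236.74,0
n-hexane,86.18,0
isoprene,68.12,0
methyl chloride,50.49,0
pentachloroethane,202.29,0
styrene,104.15,0
"1,1,1,2-tetrachloroethane",167.85,0
"1,1,2,2-tetrachloroethane",167.85,0
toluene,92.14,0
"1,1,2-trichloroethane",133.40,0
trichloroethylene,131.39,0
vinyl chloride,62.50,1
m-xylene,106.17,0
bromoform,252.73,0
dibromochloromethane,208.28,0
"trans-1,2-dichloroethylene",96.94,0
ethylene,28.05,0
furan,68.07,0
halothane,197.38,0
propylene,42.08,0
tetrachloroethylene,165.83,0
"1,1,1-trichloroethane",133.40,0
"1,2,4-trimethylbenzene",120.19,0
o-xylene,106.17,0
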
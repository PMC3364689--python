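# Regression inputs and experimental endpoint for the clearance QPPR.
# log_pow: log10 n-octanol:water PC; log_pbw: log10 blood:water PC;
# ip: calculated ionization potential (eV);
# log_clint_pl_exp: log10 in-vivo intrinsic clearance referenced to
# phospholipid (L PL/h/kg^0.75), from rat gas-uptake studies.
name,dataset,log_pow,log_pbw,ip,log_clint_pl_exp
benzene,calibration,1.99,0.820,9.743,0.667
bromochloromethane,calibration,1.43,0.642,10.562,1.118
bromodichloromethane,calibration,1.61,0.717,10.676,1.029
carbon tetrachloride,calibration,2.44,0.988,10.985,-0.700
chloroethane,calibration,1.58,0.438,10.410,0.987
chloroform,calibration,1.52,0.741,10.839,1.192
dibromomethane,calibration,1.52,0.777,10.587,1.275
"1,1-dichloroethane",calibration,1.76,0.624,10.577,0.974
"1,2-dichloroethane",calibration,1.83,0.356,10.446,0.163
"1,1-dichloroethylene",calibration,2.12,0.922,9.748,1.223
"cis-1,2-dichloroethylene",calibration,1.98,0.752,9.493,0.092
dichloromethane,calibration,1.34,0.608,10.582,0.777
ethylbenzene,calibration,3.03,1.386,9.406,-0.334
hexachloroethane,calibration,4.03,1.315,10.843,-1.767
n-hexane,calibration,3.29,2.492,11.276,0.252
isoprene,calibration,2.58,0.987,9.349,0.472
methyl chloride,calibration,1.09,0.160,10.473,0.299
pentachloroethane,calibration,3.11,1.251,10.763,-0.297
styrene,calibration,2.89,0.889,9.130,-0.088
"1,1,1,2-tetrachloroethane",calibration,2.93,0.836,10.728,-0.693
"1,1,2,2-tetrachloroethane",calibration,2.19,0.519,10.736,0.051
toluene,calibration,2.54,0.879,9.442,0.282
"1,1,2-trichloroethane",calibration,2.01,0.491,10.689,0.018
trichloroethylene,calibration,2.47,1.192,9.368,0.916
vinyl chloride,calibration,1.62,0.433,9.833,0.741
m-xylene,calibration,3.09,1.388,9.308,0.218
bromoform,evaluation,1.79,0.896,10.837,1.006
dibromochloromethane,evaluation,1.70,1.025,10.702,1.108
"trans-1,2-dichloroethylene",evaluation,1.98,0.484,9.512,0.438
ethylene,evaluation,1.27,0.776,10.638,1.208
furan,evaluation,1.36,0.441,9.375,1.773
halothane,evaluation,2.26,0.977,11.039,1.104
propylene,evaluation,1.68,0.995,10.103,1.118
tetrachloroethylene,evaluation,2.97,1.404,9.217,-1.804
"1,1,1-trichloroethane",evaluation,2.68,0.823,10.751,-2.467
"1,2,4-trimethylbenzene",evaluation,3.63,1.829,9.084,-0.132
o-xylene,evaluation,3.09,1.213,9.304,0.163
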
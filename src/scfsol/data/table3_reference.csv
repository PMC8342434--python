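eos,rule,T_K,kij,lij,Psub_bar,aard_pct
srk,vdw1,303.15,0.07979,,5.76e-6,7.54
srk,vdw1,313.15,0.119786,,0.000165,11.58
srk,vdw1,323.15,0.167963,,0.003333,9.35
srk,vdw2,303.15,0.632664,0.585396,0.267549,5.67
srk,vdw2,313.15,0.538128,0.513787,0.114635,3.64
srk,vdw2,323.15,0.602364,0.592264,0.993638,3.81
pr,vdw1,303.15,0.080396,,1.04e-5,6.96
pr,vdw1,313.15,0.116453,,2.41e-5,10.70
pr,vdw1,323.15,1.170893,,0.004242,8.68
pr,vdw2,303.15,0.181497,0.115645,6.29e-5,6.36
pr,vdw2,313.15,0.517322,0.491264,0.102111,3.62
pr,vdw2,323.15,0.583477,0.571054,0.889204,3.82
sv,vdw1,303.15,0.092516,,1.045047,6.96
sv,vdw1,313.15,0.127765,,3.81e-5,10.68
sv,vdw1,323.15,0.171397,,0.004141,8.66
sv,vdw2,303.15,0.625796,0.581154,0.266842,5.68
sv,vdw2,313.15,0.522877,0.490355,0.100798,3.62
sv,vdw2,323.15,0.546006,0.504091,0.562166,3.97
dptg,vdw1,303.15,0.353399,,0.050702,5.78
dptg,vdw1,313.15,0.325725,,0.106757,4.52
dptg,vdw1,323.15,0.34744,,0.691951,4.09
dptg,vdw2,303.15,0.353399,0.252096,0.050702,5.78
dptg,vdw2,313.15,0.391577,0.110898,0.21614,3.65
dptg,vdw2,323.15,0.364307,0.034643,0.778508,4.04
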
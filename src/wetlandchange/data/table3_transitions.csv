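ensemble,from_class,Sand dunes,Burned areas,Tidal areas,Forest,Reedbed,Sea dunes,Grasslands,Salt marshes
Ens_SV,Sand dunes,53.64,0,8.01,0,0,18.27,0,0
Ens_SV,Burned areas,0,0,0,0,0,0,0,0
Ens_SV,Tidal areas,2.97,0,50.4,0,0,0.72,0,2.07
Ens_SV,Forest,0,9.45,0,128.7,1.08,0.9,9.81,2.97
Ens_SV,Reedbed,0.27,0.36,0,1.62,7.2,2.52,4.05,1.62
Ens_SV,Sea dunes,6.3,4.23,2.16,4.14,2.7,249.03,7.56,9.27
Ens_SV,Grasslands,0,6.93,0,38.43,9.36,30.78,147.51,3.15
Ens_SV,Salt marshes,0,8.55,1.35,27.9,8.01,5.58,6.12,98.64
Ens_WV,Sand dunes,54.54,0,7.92,0,0,18.36,0,0
Ens_WV,Burned areas,0,0,0,0,0,0,0,0
Ens_WV,Tidal areas,2.97,0,50.31,0,0,0.63,0,1.89
Ens_WV,Forest,0,9.36,0,128.79,1.08,0.81,9.09,2.88
Ens_WV,Reedbed,0.18,0.36,0,2.07,7.38,2.61,4.32,1.17
Ens_WV,Sea dunes,6.39,4.41,1.53,3.96,3.06,248.76,6.57,7.74
Ens_WV,Grasslands,0,6.93,0,40.5,10.71,32.31,147.69,2.7
Ens_WV,Salt marshes,0,8.37,1.44,28.62,8.01,5.85,4.95,97.11
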
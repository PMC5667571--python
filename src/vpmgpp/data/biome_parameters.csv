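# Biome-specific VPM parameters keyed by IGBP land-cover class.
# eps0 in g C per mol APAR (C4 value empty where the pathway split is
# not defined for the class); temperatures in degC.
code,igbp,eps0_c3,eps0_c4,t_min,t_max,t_opt
1,ENF,0.42,,-1,40,20
2,EBF,0.42,,-2,48,28
3,DNF,0.42,,-1,40,20
4,DBF,0.42,,-1,40,20
5,MF,0.42,,-1,48,19
6,CSH,0.42,,-1,48,25
7,OSH,0.42,,1,48,31
8,WSA,0.42,,-1,48,24
9,SAV,0.42,0.63,1,48,30
10,GRA,0.42,0.63,0,48,27
11,WET,0.42,0.63,-1,40,20
12,CRO,0.42,0.63,-1,48,30
13,URB,0.42,,0,48,27
14,CNV,0.42,0.63,0,48,27
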
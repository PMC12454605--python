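mouse,sex,lifespan_months,censored,E_asc_kPa,E_desc_kPa,ATI
1,M,17.8,0,722,3470,45.34
2,M,18.2,0,1164,719,59.53
3,M,22.3,0,712,2210,37.87
4,M,13.2,0,746,4418,52.03
5,F,21.9,0,388,1867,53.57
6,F,25,1,1595,781,39.86
7,F,12.3,0,711,3748,35.44
8,F,25,1,930,961,38.78
9,F,25,1,644,631,22.8
10,M,25,1,1033,684,28.74
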
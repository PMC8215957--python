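combination,time_to_peak_ms,peak_velocity_m_s,pct_difference
1,1.5,5,-12
2,3.5,5,-19
3,5,5,-12
4,7,5,-14
5,9,5,-14
6,1.5,11.25,-24
7,3.5,11.25,-22
8,5,11.25,-21
9,7,11.25,-23
10,9,11.25,-22
11,1.5,17.5,-22
12,3.5,17.5,-22
13,5,17.5,-23
14,7,17.5,-21
15,9,17.5,-25
16,1.5,23.75,-22
17,3.5,23.75,-21
18,5,23.75,-24
19,7,23.75,-19
20,9,23.75,-18
21,1.5,30,-15
22,3.5,30,-19
23,5,30,-19
24,7,30,-17
25,9,30,-18
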
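combination,delta_p_minor,delta_p_major
1,-6,-1
2,-11,-2
3,-6,-2
4,-9,-2
5,-10,-3
6,-37,-46
7,-36,-50
8,-34,-45
9,-30,-54
10,-25,-39
11,-19,-50
12,-18,-47
13,-13,-42
14,-14,-43
15,-12,-42
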
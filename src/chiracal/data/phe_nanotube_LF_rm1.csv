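i,Dx,Dy,Dz,D
1,2.625,-0.697,0.282,2.73
2,2.884,0.36,-1.765,3.4
3,1.645,1.503,1.106,2.488
4,1.71,1.869,0.65,2.615
5,-0.76,2.203,1.054,2.558
6,-0.956,2.224,0.37,2.449
7,-1.096,0.851,-2.656,2.997
8,-1.456,0.79,-1.534,2.258
9,-1.265,-1.928,-0.785,2.436
10,-1.789,-1.795,0.63,2.611
11,-0.942,-0.771,-1.442,1.887
12,-0.996,-1.873,0.586,2.201
Dsum,-0.396,3.433,-3.504,30.63
Dcoil,6.624,2.82,-6.934,9.995
Dav,,,,2.553
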
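i,Dx,Dy,Dz,D
1,-2.109,1.87,1.142,3.041
2,-2.724,-0.862,-0.846,2.98
3,-1.612,-1.66,-1.443,2.727
4,-0.79,-2.055,1.726,2.797
5,1.098,-2.542,0.245,2.78
6,1.285,-2.357,-1.726,3.192
7,1.197,-2.894,1.953,3.691
8,2.07,1.06,-0.539,2.387
9,1.376,1.563,1.353,2.483
10,-0.748,2.323,1.23,2.732
11,-2.448,1.774,0.547,3.072
12,-2.774,0.589,0.034,2.836
Dsum,-6.179,-3.191,3.675,34.718
Dcoil,-4.333,-5.081,4.818,8.234
Dav,,,,2.893
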
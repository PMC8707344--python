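i,Dx,Dy,Dz,D
1,-2.037,2.152,0.414,2.992
2,-3.516,-0.872,-0.63,3.676
3,-2.084,-1.822,-0.735,2.864
4,0.259,-2.654,1.244,2.943
5,0.852,-2.59,-0.325,2.746
6,1.415,-2.392,-0.483,2.821
7,1.444,-3.251,1.282,3.781
8,1.317,2.048,0.578,2.503
9,1.72,1.513,1.758,2.888
10,-1.128,2.525,1.766,3.282
11,-3.239,1.798,0.657,3.762
12,-2.229,0.793,-1.231,2.667
Dsum,-7.224,-2.752,4.294,36.925
Dcoil,-6.395,-5.676,4.362,9.599
Dav,,,,3.077
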
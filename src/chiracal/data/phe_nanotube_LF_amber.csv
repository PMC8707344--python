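i,Dx,Dy,Dz,D
1,2.74,-0.955,-0.282,2.915
2,2.232,1.075,-1.578,2.937
3,0.984,1.348,2.025,2.624
4,2.086,1.603,0.463,2.671
5,-1.325,1.618,1.928,2.844
6,-0.554,2.429,-0.608,2.564
7,-1.185,-0.194,-2.046,2.372
8,-0.631,0.534,-1.406,1.631
9,-2.137,-1.636,-0.026,2.691
10,-1.081,-0.999,0.31,1.504
11,-1.135,-0.254,0.068,1.165
12,-0.819,-1.533,-0.338,1.771
Dsum,2.111,3.036,-2.138,27.692
Dcoil,4.2597,2.0522,-4.164,6.3004
Dav,,,,2.308
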
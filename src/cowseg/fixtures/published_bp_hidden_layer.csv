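neuron,age,top_view_height,top_view_area,back_view_distance,back_view_area,bias
1,-0.7168,1.7498,1.0712,0.2550,0.0099,2.2288
2,1.5923,1.4301,-0.0613,-0.3326,-0.1688,1.9718
3,-1.0202,1.1312,1.1350,-0.2815,0.2398,-1.1727
4,1.4218,0.1317,1.2314,-1.2518,1.6771,0.4229
5,0.3109,0.8227,0.1027,-1.3699,-1.2313,-0.0952
6,-1.6136,-0.8355,1.2502,1.4542,-0.4391,0.4524
7,-0.5799,0.2280,1.3392,1.4404,0.3207,-0.0802
8,-0.8586,2.2939,-1.1279,-1.1543,0.3060,-1.1329
9,1.0519,0.6161,0.3122,1.1347,1.0746,-2.2368
10,0.8432,0.7209,-0.8869,-1.3034,0.4020,2.0389
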
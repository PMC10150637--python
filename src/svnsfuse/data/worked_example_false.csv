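instance,AK,BCC,BKL,DF,MEL,NV,SCC,VASC
1,0.999827,0.99999,0.998686,0.999999,0.974136,0.004948,0.999997,0.999897
2,0.999998,0.999967,0.998741,0.999854,0.032554,0.991417,0.999699,0.999431
3,0.999978,0.999988,0.998547,0.999833,0.686364,0.301565,0.99951,1
4,0.999598,0.998762,0.996136,0.999917,0.304397,0.431489,0.99994,0.999985
5,0.999527,0.99961,0.996572,0.999958,0.00835,0.97419,0.999923,0.998474
6,0.999643,0.996873,0.895743,0.997799,0.995986,0.934151,0.781645,1
7,0.99969565,0.99934214,0.42656824,0.94402712,0.97042959,0.76180088,0.99688428,0.99993538
8,0.99988746,0.03310882,0.98594981,0.99999880,0.77315056,0.99997746,0.99433112,0.99966990
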
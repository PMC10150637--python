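instance,AK,BCC,BKL,DF,MEL,NV,SCC,VASC
1,6.27E-09,1.38E-07,4.45E-05,2.8E-06,0.007004,0.983134,2.04E-06,3.44E-06
2,1.5E-09,0.002268,1.14E-05,2.82E-07,0.991507,3.46E-07,4.74E-07,7.79E-07
3,2.79E-08,1.04E-07,1.85E-06,5.24E-05,0.91627,0.431186,2.52E-06,3.94E-08
4,1.79E-07,3.5E-09,5.21E-08,4.74E-05,0.730593,0.750079,5.19E-07,3.58E-08
5,5.67E-07,0.00043,0.000133,3.69E-09,0.004654,0.858638,5.46E-05,9.5E-05
6,1.24E-09,0.21793,0.131226,0.002955,0.015759,6.38E-06,0.005419,5.97E-07
7,2.88374E-05,4.33938E-07,0.13733686,0.00021989,0.03810337,0.41384637,0.00015349,5.45065E-06
8,1.66308E-06,0.81519597,1.80939E-09,2.78238E-10,0.96386611,3.09955E-07,6.69544E-06,9.52509E-07
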
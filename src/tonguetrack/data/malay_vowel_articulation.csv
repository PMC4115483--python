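vowel,gender,parameter,f1,f2,f3,f4,f5,f6,f7,mean,std,variance
a,M,TTCL,19.47,21.57,25.25,28.67,27.88,24.73,20.78,24.05,3.5528,12.6226
a,M,TBCL,9.47,13.42,11.84,12.63,5.26,12.1,10.26,10.7114,2.7593,7.6137
a,M,LA,11.31,12.63,12.1,12.36,11.31,12.63,11.84,12.0257,0.5637,0.3178
a,F,TTCL,17.01,25.42,27.7,30.5,29.1,27.35,24.37,25.9214,4.4411,19.7238
a,F,TBCL,6.66,8.24,10.69,12.27,10.34,12.27,8.06,9.79,2.1835,4.7676
a,F,LA,4.91,8.76,13.32,15.42,10.86,12.09,5.08,10.0629,4.0235,16.1885
e,M,TTCL,11.57,12.63,13.68,14.73,16.05,14.47,13.15,13.7543,1.4799,2.1901
e,M,TBCL,8.21,9.79,8.47,11.36,11.1,7.94,10.05,9.56,1.3868,1.9233
e,M,LA,9.73,11.57,11.31,11.05,13.42,12.1,12.1,11.6114,1.1325,1.2826
e,F,TTCL,13.6,19.03,21.13,23.23,27.09,22.88,20.78,21.1057,4.1678,17.3706
e,F,TBCL,7.23,6.88,7.75,8.63,8.98,7.75,8.63,7.9786,0.7877,0.6205
e,F,LA,1.58,5.08,10.34,11.74,13.84,12.97,12.97,9.7886,4.6605,21.7201
ə,M,TTCL,12.31,15.47,19.68,21.52,25.47,23.63,20.73,19.83,4.5734,20.9164
ə,M,TBCL,6.09,4.51,7.93,9.25,10.56,9.25,11.88,8.4957,2.5445,6.4743
ə,M,LA,6.58,6.84,6.58,8.15,7.1,7.89,9.47,7.5157,1.06,1.1237
ə,F,TTCL,13.67,21.38,23.48,25.76,30.67,25.06,22.6,23.2314,5.1701,26.7298
ə,F,TBCL,3.33,5.96,5.78,5.96,7.01,5.96,6.13,5.7329,1.1343,1.2866
ə,F,LA,3.86,11.74,10.34,8.76,12.27,7.71,10.51,9.3129,2.879,8.2887
i,M,TTCL,6.31,5.52,6.05,6.05,6.84,6.84,8.15,6.5371,0.851,0.7243
i,M,TBCL,1.84,2.37,3.16,4.21,5.79,3.68,1.84,3.27,1.4326,2.0523
i,M,LA,6.84,5.26,6.84,8.94,7.1,6.05,7.89,6.9886,1.1935,1.4243
i,F,TTCL,15.77,16.3,20.33,15.77,16.82,18.05,11.74,16.3971,2.6097,6.8105
i,F,TBCL,1.05,1.58,2.1,2.28,1.93,1.4,1.23,1.6529,0.4622,0.2136
i,F,LA,10.51,12.44,0.18,10.69,1.75,12.09,12.79,8.6357,5.3277,28.3847
o,M,TTCL,14.21,24.46,31.83,29.99,23.15,12.63,11.05,21.0457,8.4642,71.642
o,M,TBCL,5.67,10.14,8.04,8.04,8.3,4.36,8.3,7.55,1.9159,3.6706
o,M,LA,4.74,6.31,4.47,5.79,6.31,4.74,4.47,5.2614,0.8441,0.7125
o,F,TTCL,22.25,24.36,25.58,27.69,30.67,29.09,26.99,26.6614,2.8595,8.1765
o,F,TBCL,5.71,5.53,7.46,6.94,6.24,6.94,7.99,6.6871,0.9052,0.8194
o,F,LA,11.74,3.5,11.92,11.92,12.97,11.04,8.94,10.29,3.2426,10.5146
u,M,TTCL,15.26,24.73,26.04,28.94,26.04,24.73,16.84,23.2257,5.1194,26.2082
u,M,TBCL,4.74,4.74,3.16,4.74,3.95,4.74,3.16,4.1757,0.7514,0.5647
u,M,LA,3.68,1.84,2.1,3.16,2.63,4.47,6.05,3.4186,1.4729,2.1696
u,F,TTCL,18.92,21.55,28.04,29.61,31.19,28.56,25.06,26.1329,4.4976,20.2287
u,F,TBCL,3.68,2.45,2.98,1.93,8.41,2.8,3.86,3.73,2.169,4.7046
u,F,LA,2.98,1.75,1.93,2.45,8.76,1.75,1.75,3.0529,2.5591,6.5489
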
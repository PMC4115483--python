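vowel,f1_male,f1_male_sd,f1_female,f1_female_sd,f2_male,f2_male_sd,f2_female,f2_female_sd
a,420.48,13.57,767.95,12.25,1231.05,25.17,1562.41,27.54
e,358.12,6.03,692.99,7.03,1578.04,24.33,2059.27,22.54
ə,333.12,2.72,654.43,2.34,1324.39,50.29,1711.98,48.65
i,228.99,0.60,490.61,0.04,1738.69,4.63,2624.81,4.21
o,371.59,5.26,620.58,5.65,918.09,2.03,1245.83,2.38
u,326.49,5.21,502.72,4.86,754.98,25.44,1157.55,23.76
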
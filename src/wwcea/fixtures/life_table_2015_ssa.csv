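# Abridged sex-averaged annual death probabilities, 2015 US period life table
# (Social Security Administration actuarial tables). Values are approximate
# transcriptions at 5-year age anchors, averaged over male and female qx;
# lookups interpolate linearly between anchors.
age,annual_death_probability
40,0.001685
45,0.002600
50,0.004055
55,0.006050
60,0.008890
65,0.013090
70,0.020205
75,0.031745
80,0.051390
85,0.086815
90,0.146480
95,0.237185
100,0.345225
105,0.464175
110,0.571650
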
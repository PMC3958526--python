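Y: 0.0
d_E: 0.1
d_N: 0.1
d_OS: 0.1
d_R: 0.1
h: 2.0
i_N: 1.0
i_OS: 1.0
i_R: 1.0
k: 50.0
k_Y: 20.0
n: 2.0
p: 15.0
s12: 12.0
s3: 0.4
s4: 43.0
s5: 0.2
s6: 15.0
s7: 2.0
sigma_N: 0.1875
sigma_OS: 0.05
sigma_R: 0.1
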
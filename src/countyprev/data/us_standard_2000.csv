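age_group,population
20-34,58855725
35-44,45148527
45-54,37677952
55-64,24274684
65-74,18390986
75+,16600767
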
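mz,charge,ccs_n2
118.0863,1,121.30
322.0481,1,153.73
622.0290,1,202.96
922.0098,1,243.64
1221.9906,1,282.20
1521.9715,1,316.86
1821.9523,1,351.55
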
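7-0
1 0.5 0.1 0.01 0.1 0.01
0.5 1 0.5 0.1 0.5 0.01
0.1 0.5 1 0.5 0.5 0.1
0.01 0.1 0.5 1 0.5 0.5
0.1 0.5 0.5 0.5 1 0.1
0.01 0.01 0.1 0.5 0.1 1
END
11-7
1 0.5 0.01 0.01 0.01 0.01
0.5 1 0.5 0.1 0.7 0.01
0.01 0.5 1 0.1 0.5 0.01
0.01 0.1 0.1 1 0.5 0.5
0.01 0.7 0.5 0.5 1 0.1
0.01 0.01 0.01 0.5 0.1 1
END
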
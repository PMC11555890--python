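element,sigma,epsilon
C,3.400,0.0860
N,3.250,0.1700
O,2.960,0.2100
H,2.420,0.0300
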
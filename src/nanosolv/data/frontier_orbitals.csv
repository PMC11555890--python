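species,homo,lumo,printed_eg,printed_delta_eg_pct
D(IMA),-0.2729,0.0072,0.2801,
CNT,-0.1839,-0.0962,0.0877,
CNT-OH,-0.1866,-0.1121,0.0745,-15.05
CNT-COOH,-0.1869,-0.1101,0.0768,-12.44
CNT-D,-0.1893,-0.0966,0.0927,5.74
CNT-OH-D(CO),-0.1883,-0.1098,0.0785,5.38
CNT-COOH-D(CO),-0.1864,-0.1064,0.0800,4.21
CNT-OH-D(PY),-0.1848,-0.1071,0.0777,4.36
CNT-COOH-D(PY),-0.1830,-0.1015,0.0816,6.28
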
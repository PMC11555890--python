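species,dg_sol,printed_dg_ass
D(IMA),-27.21,
CNT,-8.882,
CNT-OH,-109.38,
CNT-COOH,-104.49,
CNT-D,-73.53,37.438
CNT-OH-D(CO),-114.62,-21.97
CNT-COOH-D(CO),-119.77,-11.93
CNT-OH-D(PY),-60.25,-76.34
CNT-COOH-D(PY),-56.24,-75.46
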
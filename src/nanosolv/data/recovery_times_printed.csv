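species,nu_hz,printed_value,printed_unit
CNT-OH-D(CO),1e12,214.4,day
CNT-COOH-D(CO),1e12,1.2,s
CNT-OH-D(PY),1e12,43.9,ms
CNT-COOH-D(PY),1e12,41.7,ms
CNT-OH-D(CO),1e13,21.4,day
CNT-COOH-D(CO),1e13,0.12,s
CNT-OH-D(PY),1e13,4.4,ms
CNT-COOH-D(PY),1e13,4.2,ms
CNT-OH-D(CO),1e14,51.4,h
CNT-COOH-D(CO),1e14,11.6,ms
CNT-OH-D(PY),1e14,0.4,ms
CNT-COOH-D(PY),1e14,0.4,ms
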
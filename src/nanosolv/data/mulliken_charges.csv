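species,q_O4,q_O2,q_C1,q_H3,q_O6,q_N
D(IMA),-0.821,,,,,-0.640
CNT-OH,,-0.583,0.137,0.314,,
CNT-COOH,,-0.634,1.029,0.375,-0.738,
CNT-D,-0.839,,,,,-0.640
CNT-OH-D(CO),-0.906,-0.564,0.159,0.425,,-0.646
CNT-COOH-D(CO),-0.959,-0.657,1.08,0.469,-0.803,-0.612
CNT-OH-D(PY),-0.890,-0.643,0.178,0.430,,-0.751
CNT-COOH-D(PY),-0.829,-0.724,1.060,0.486,-0.773,-0.800
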
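species,dipole_debye,binding_energy,[C-O4],[C1-O2],[C1-O6],[O2-H3]
D(IMA),5.39,,1.228,,,
CNT,0.00,,,,,
CNT-OH,7.15,,,1.476,,0.999
CNT-COOH,6.80,,,1.377,1.219,0.997
CNT-D,6.01,-58.56,,,,
CNT-OH-D(CO),7.14,-26.27,1.258,1.463,,1.016
CNT-COOH-D(CO),12.37,-16.45,1.2652,1.34,1.235,1.032
CNT-OH-D(PY),10.05,-14.51,,1.446,,1.033
CNT-COOH-D(PY),13.76,-14.48,,1.326,1.237,1.109
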
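# piperazine C4H10N2: chair geometry (ETKDG seed 20240901 + MMFF94 optimization),
# MMFF94 partial charges, GAFF sp3 Lennard-Jones parameters (sigma A, epsilon kJ/mol)
# element x y z q sigma epsilon
C 0.709353 1.234078 -0.065218 0.270000 3.399670 0.457730  # c3
C 1.375996 -0.088867 0.359328 0.270000 3.399670 0.457730  # c3
N 0.778203 -1.280981 -0.268146 -0.900000 3.249999 0.711280  # n3
C -0.644334 -1.072756 -0.581902 0.270000 3.399670 0.457730  # c3
C -1.346662 -0.020638 0.301099 0.270000 3.399670 0.457730  # c3
N -0.722343 1.311658 0.276025 -0.900000 3.249999 0.711280  # n3
H 1.225167 2.074983 0.410568 0.000000 2.471353 0.065689  # h1
H 0.826180 1.361385 -1.149123 0.000000 2.471353 0.065689  # h1
H 2.441317 -0.061460 0.106540 0.000000 2.471353 0.065689  # h1
H 1.310427 -0.188024 1.450466 0.000000 2.471353 0.065689  # h1
H 0.873264 -2.061596 0.380586 0.360000 1.069078 0.065689  # hn
H -0.721067 -0.766409 -1.632504 0.000000 2.471353 0.065689  # h1
H -1.170383 -2.030689 -0.500467 0.000000 2.471353 0.065689  # h1
H -1.355693 -0.374089 1.339604 0.000000 2.471353 0.065689  # h1
H -2.395563 0.072378 -0.002463 0.000000 2.471353 0.065689  # h1
H -1.183861 1.891026 -0.424393 0.360000 1.069078 0.065689  # hn
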
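# SPC/E water oxygen Lennard-Jones site (Berendsen et al. 1987).
# epsilon = 0.1553 kcal/mol converted at 4.184 kJ/kcal.

model = "SPC/E"

[[site]]
name = "O-SPC/E"
epsilon_kJmol = 0.6497752
sigma_nm = 0.3166
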
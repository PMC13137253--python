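# OPC water oxygen Lennard-Jones site (Izadi, Anandakrishnan & Onufriev 2014).
# epsilon = 0.2128 kcal/mol converted at 4.184 kJ/kcal.

model = "OPC"

[[site]]
name = "O-OPC"
epsilon_kJmol = 0.8903552
sigma_nm = 0.316655
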
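# OPC3 water oxygen Lennard-Jones site (Izadi & Onufriev 2016).
# epsilon = 0.163406 kcal/mol converted at 4.184 kJ/kcal.

model = "OPC3"

[[site]]
name = "O-OPC3"
epsilon_kJmol = 0.6836907
sigma_nm = 0.317427
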
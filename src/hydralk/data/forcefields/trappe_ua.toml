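# TraPPE-UA united-atom alkane Lennard-Jones sites (Martin & Siepmann 1998).
# Schema: one [[site]] block per site; epsilon given either as
# epsilon_kJmol (kJ/mol) or epsilon_over_kB_K (Kelvin); sigma_nm in nm.

model = "TraPPE-UA"

[[site]]
name = "CH4"
epsilon_over_kB_K = 148.0
sigma_nm = 0.373

[[site]]
name = "CH3"
epsilon_over_kB_K = 98.0
sigma_nm = 0.375

[[site]]
name = "CH2"
epsilon_over_kB_K = 46.0
sigma_nm = 0.395
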
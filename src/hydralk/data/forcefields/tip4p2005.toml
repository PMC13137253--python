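# TIP4P/2005 water oxygen Lennard-Jones site (Abascal & Vega 2005).

model = "TIP4P/2005"

[[site]]
name = "O-TIP4P/2005"
epsilon_over_kB_K = 93.2
sigma_nm = 0.31589
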
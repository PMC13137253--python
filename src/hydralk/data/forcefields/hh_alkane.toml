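# HH-alkane united-atom pair well depths with TIP4P/2005 water oxygen
# (Ashbaugh et al.; "thermal radius" sigma values are not published in a
# tabulated form here, so sigma_nm is intentionally absent and must be
# supplied by the user when a geometry is required).

model = "HH-alkane"
pairwise = true

[[site]]
name = "CH4:O"
epsilon_kJmol = 0.9765

[[site]]
name = "CH3:O"
epsilon_kJmol = 0.7946

[[site]]
name = "CH2:O"
epsilon_kJmol = 0.5444
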
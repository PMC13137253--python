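# Alkane-water Lennard-Jones well depths (kJ/mol): Lorentz-Berthelot values
# ("original") and the cavity-reparameterized values ("updated") for each
# water model; HH-alkane pair values listed for comparison.
water_model,pair,eps_original,eps_updated
SPC/E,CH4:O,0.8942,0.9436
SPC/E,CH3:O,0.7276,0.7679
SPC/E,CH2:O,0.4985,0.5261
OPC3,CH4:O,0.9172,0.9668
OPC3,CH3:O,0.7464,0.7867
OPC3,CH2:O,0.5114,0.5390
OPC,CH4:O,1.0467,1.0841
OPC,CH3:O,0.8517,0.8822
OPC,CH2:O,0.5835,0.6044
TIP4P/2005,CH4:O,0.9765,1.0169
TIP4P/2005,CH3:O,0.7946,0.8274
TIP4P/2005,CH2:O,0.5444,0.5669
HH-alkane,CH4:O,0.9765,1.0226
HH-alkane,CH3:O,0.7946,0.8224
HH-alkane,CH2:O,0.5444,0.5652
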
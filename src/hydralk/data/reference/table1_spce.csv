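# Hydration free-energy decomposition for linear alkanes, TraPPE-UA + SPC/E,
# T = 300 K, all energies in kJ/mol. dg_hyd_exp: experimental / group
# contribution hydration free energy; dg_hyd_model: FEP result with the
# original Lorentz-Berthelot parameters; dg_cavity: cavity formation free
# energy (taken from prior cavity studies); dh_att_model: alkane-water
# attraction enthalpy of the original model; dh_att_exp / dh_att_updated /
# dg_pred: published derived columns (retained for pinning tests);
# dg_hyd_sim: hydration free energy re-simulated with the updated well depth
# (blank where not run).
n_carbons,dg_hyd_exp,dg_hyd_model,dg_cavity,dh_att_exp,dh_att_model,dh_att_updated,dg_pred,dg_hyd_sim,provenance
1,8.37,9.39,24.52,-16.15,-15.12,-15.96,8.56,8.53,published-table
2,7.66,9.28,34.87,-27.21,-25.59,-27.01,7.86,7.57,published-table
3,8.18,9.94,43.85,-35.67,-33.91,-35.78,8.07,8.47,published-table
4,8.70,11.16,52.55,-43.85,-41.39,-43.68,8.87,8.89,published-table
5,9.76,12.19,61.86,-52.10,-49.67,-52.42,9.44,,published-table
6,10.40,13.11,70.34,-59.94,-57.23,-60.40,9.94,10.34,published-table
8,12.10,15.69,87.72,-75.62,-72.03,-76.01,11.71,,published-table
10,13.32,18.08,105.75,-92.43,-87.68,-92.53,13.23,13.47,published-table
12,14.80,20.15,123.36,-108.56,-103.21,-108.92,14.44,,published-table
14,16.28,22.95,140.80,-124.52,-117.85,-124.37,16.43,17.34,published-table
16,17.76,25.15,157.81,-140.05,-132.66,-140.00,17.81,,published-table
18,19.24,27.64,174.72,-155.48,-147.08,-155.21,19.51,19.90,published-table
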
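# USLE/MUSS plot factors used for the trials: K = 0.12 (sandy loam, OM > 2%),
# LS from slope length/steepness per trial, P = 1, plot areas 72 m2 (2018,
# 2013) and 54 m2 (2019).
trial,slope_pct,area_ha,k_factor,ls_factor,p_factor
2018,9,0.0072,0.12,1.05,1
2019,9,0.0054,0.12,0.90,1
2013,16,0.0072,0.12,2.25,1
2013,9,0.0072,0.12,1.05,1
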
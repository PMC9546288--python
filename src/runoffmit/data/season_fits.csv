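# Whole-season calibration results for the same trials: fitted runoff curve
# number and MUSS C-factor per treatment arm, with the seasonal erosion and
# runoff totals the fits reproduce (simulated vs measured).
trial,slope_pct,treatment,cn,c_factor,erosion_sim_t_ha,erosion_meas_t_ha,runoff_sim_mm,runoff_meas_mm
2018,9,CvT,80,7.17,2.37,2.37,8.10,7.30
2018,9,MD+CvT,75,7.14,1.05,1.05,4.60,4.15
2018,9,CsT,66,2.33,0.06,0.06,1.40,1.22
2018,9,MD+CsT,64,2.03,0.03,0.03,0.80,0.66
2019,9,CvT,74,16.2,6.70,6.70,10.60,9.70
2019,9,MD+CvT,67,13.8,1.20,1.20,3.90,3.30
2019,9,CsT,66,9.10,0.60,0.60,3.20,3.00
2019,9,MD+CsT,63,7.00,0.20,0.20,1.70,1.54
2013,16,CvT,81,0.74,1.04,1.03,7.41,7.28
2013,16,MD_disc,80,0.45,0.49,0.48,6.17,5.51
2013,16,MD_drum,76,0.79,0.26,0.26,2.76,2.30
2013,16,CsT,72,0.27,0.02,0.02,0.91,0.78
2013,9,CvT,79,1.23,0.42,0.42,5.15,4.78
2013,9,MD_disc,76,1.20,0.17,0.17,2.76,2.54
2013,9,MD_drum,74,1.12,0.08,0.08,1.67,1.38
2013,9,CsT,71,1.00,0.02,0.02,0.64,0.62
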
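# Measured seasonal totals and event-wise precipitation-weighted curve numbers
# for the three Belgian maize mitigation trials (Huldenberg; seasons 2018,
# 2019 and 2013, the 2013 trial with a 16% and a 9% slope series).
# Treatments: CvT conventional tillage, CsT conservation tillage (subsoiler),
# MD micro-dams (2013: separate disc-plow and drum-plow devices).
trial,slope_pct,treatment,runoff_mm,cn_eventwise,erosion_kg_ha
2018,9,CvT,7.3,75,2371
2018,9,MD+CvT,4.2,72,1046
2018,9,CsT,1.2,67,62
2018,9,MD+CsT,0.7,66,34
2019,9,CvT,9.7,73,6655
2019,9,MD+CvT,3.3,70,1203
2019,9,CsT,3.0,66,599
2019,9,MD+CsT,1.5,65,204
2013,16,CvT,7.3,69,1030
2013,16,MD_disc,5.5,68,480
2013,16,MD_drum,2.3,63,260
2013,16,CsT,0.78,63,17
2013,9,CvT,4.8,67,420
2013,9,MD_disc,2.5,66,170
2013,9,MD_drum,1.4,64,80
2013,9,CsT,0.62,63,17
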
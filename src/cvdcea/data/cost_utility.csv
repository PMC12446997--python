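term,cost,utility
intercept,4800.0,0.845
age_minus45,55.0,-0.0015
male,-300.0,0.012
race_Black,150.0,-0.010
race_Hispanic,-250.0,-0.005
race_Asian,-350.0,0.005
race_Other,0.0,-0.008
income_poor,600.0,-0.040
income_near_poor,450.0,-0.030
income_low,250.0,-0.020
income_medium,100.0,-0.008
edu_no_degree,400.0,-0.030
edu_ged_hs,200.0,-0.015
edu_associate_bachelor,50.0,-0.005
cvd_history,3600.0,-0.070
event_cycle,0.0,-0.110
diabetes,1800.0,-0.030
bmi_minus28,40.0,-0.002
smoker,350.0,-0.015
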
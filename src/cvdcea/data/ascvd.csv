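sex,race,term,value
male,white,ln_age,4.50
male,white,ln_sbp_untreated,1.85
male,white,ln_sbp_treated,1.95
male,white,ln_total_chol,1.20
male,white,ln_hdl_chol,-1.00
male,white,smoker,0.65
male,white,diabetes,0.66
male,white,baseline_survival_10yr,0.91
male,black,ln_age,2.50
male,black,ln_sbp_untreated,1.80
male,black,ln_sbp_treated,1.90
male,black,ln_total_chol,0.30
male,black,ln_hdl_chol,-0.30
male,black,smoker,0.55
male,black,diabetes,0.60
male,black,baseline_survival_10yr,0.89
female,white,ln_age,5.00
female,white,ln_sbp_untreated,2.00
female,white,ln_sbp_treated,2.10
female,white,ln_total_chol,1.00
female,white,ln_hdl_chol,-1.10
female,white,smoker,0.70
female,white,diabetes,0.80
female,white,baseline_survival_10yr,0.95
female,black,ln_age,3.00
female,black,ln_sbp_untreated,2.20
female,black,ln_sbp_treated,2.30
female,black,ln_total_chol,0.40
female,black,ln_hdl_chol,-0.40
female,black,smoker,0.60
female,black,diabetes,0.90
female,black,baseline_survival_10yr,0.93
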
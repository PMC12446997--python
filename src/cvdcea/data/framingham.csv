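sex,event,term,value
male,mi,ln_age,5.0
male,mi,ln_sbp_untreated,1.80
male,mi,ln_sbp_treated,2.00
male,mi,ln_total_chol,1.05
male,mi,ln_hdl_chol,-0.90
male,mi,smoker,0.60
male,mi,diabetes,0.55
male,mi,baseline_survival_1yr,0.9985
female,mi,ln_age,5.4
female,mi,ln_sbp_untreated,1.90
female,mi,ln_sbp_treated,2.10
female,mi,ln_total_chol,1.00
female,mi,ln_hdl_chol,-1.00
female,mi,smoker,0.70
female,mi,diabetes,0.75
female,mi,baseline_survival_1yr,0.9993
male,stroke,ln_age,5.8
male,stroke,ln_sbp_untreated,1.90
male,stroke,ln_sbp_treated,2.10
male,stroke,ln_total_chol,0.30
male,stroke,ln_hdl_chol,-0.40
male,stroke,smoker,0.50
male,stroke,diabetes,0.70
male,stroke,baseline_survival_1yr,0.9995
female,stroke,ln_age,6.0
female,stroke,ln_sbp_untreated,2.00
female,stroke,ln_sbp_treated,2.20
female,stroke,ln_total_chol,0.25
female,stroke,ln_hdl_chol,-0.45
female,stroke,smoker,0.55
female,stroke,diabetes,0.85
female,stroke,baseline_survival_1yr,0.9995
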
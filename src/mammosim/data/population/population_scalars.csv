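name,value
birth_age_mean,26.0
birth_age_sd,5.5
ever_breastfed_prob,0.6
smoker_prob,0.15
oc_ever_prob,0.8
ht_ever_prob,0.4
prs_mean,0.0
prs_sd,1.0
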
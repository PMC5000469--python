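# The eight published first-year withdrawal-risk rules, one per line.
# Rules 1-4 are risk increasing, rules 5-8 risk decreasing.
maternal_age < 27.5 AND country != Finland
smoking == yes AND risk_perception != accurate AND anxiety_score > 45
anxiety_score > 45 AND dad_participation == no
maternal_age < 27.5 AND risk_perception != accurate AND alcohol_per_month < 2
employment == yes AND smoking == no
country != Finland AND alcohol_per_month > 0 AND negative_life_events < 2
smoking == no AND anxiety_score < 45 AND n_missing <= 1
maternal_age > 27.5 AND smoking == no AND n_missing <= 1
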
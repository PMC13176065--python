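quantity	value
n_evaluable	1
mean_days	253
median_days	253
q1_days	253
q3_days	253
within_365_count	1
within_365_pct	100
bin_0-30	0
bin_31-90	0
bin_91-180	0
bin_181-365	1
bin_366-730	0
bin_>730	0
excluded_missing_start_date	1
excluded_negative_interval	1
excluded_partial_start_date	1
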
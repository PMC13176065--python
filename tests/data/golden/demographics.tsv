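section	category	count
total	cohort_reports	4
total	descriptive_n	4
sex	M	4
age_group	<18	4
occupation	PH	4
country	US	4
year	2023	4
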
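term	level	n_cases	ror	ror_lo	ror_hi	prr	chi2	ic	ic025	expected	ebgm	eb05	eligible	flag_ror	flag_prr	flag_bcpnn	flag_ebgm	consensus
General disorders	SOC	3	3	0.3120472169	28.84178904	2	0.9333333333	0.2789008113	-1.462915258	2.142857143	1.399894833	1.375012844	True	False	False	False	False	False
Respiratory disorders	SOC	2	1.5	0.1455258548	15.46117013	1.333333333	0.1166666667	0.04193068047	-1.954256535	1.714285714	1.399828503	1.37494623	False	False	False	False	False	False
Nervous system disorders	SOC	1	0.2	0.01553025449	2.575617807	0.3333333333	1.659259259	-0.7210991887	-2.960881958	2.142857143	1.399563245	1.374684224	False	False	False	False	False	False
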
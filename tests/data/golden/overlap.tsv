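algorithms	n_signals
BCPNN	0
BCPNN&EBGM	0
EBGM	0
PRR	0
PRR&BCPNN	0
PRR&BCPNN&EBGM	0
PRR&EBGM	0
ROR	0
ROR&BCPNN	0
ROR&BCPNN&EBGM	0
ROR&EBGM	0
ROR&PRR	0
ROR&PRR&BCPNN	0
ROR&PRR&BCPNN&EBGM	0
ROR&PRR&EBGM	0
consensus	0
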
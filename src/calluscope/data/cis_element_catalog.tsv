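name	pattern	category
TATA-box	TATA	core
CAAT-box	CCAAT	core
Box4	ATTAAT	light
GATA-motif	GATA	light
AT1-motif	AATTATTTTTTATT	light
ABRE	ACGTG	hormone
TGACG-motif	TGACG	hormone
TCA-element	CCATCTTTTT	hormone
P-box	CCTTTTG	hormone
as-1	TGACG	stress
ARE	AAACCA	stress
WUN-motif	AAATTTCCT	stress
TC-rich_repeats	ATTTTCTTCA	stress
STRE	AGGGG	stress
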
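gene	protein_change	chrom	pos	ref	alt
KRAS	G12C
KRAS	G12A
KRAS	G12D
KRAS	G12V
KRAS	G12S
KRAS	G13D
KRAS	Q61H
KRAS	Q61L
NRAS	Q61L
NRAS	Q61K
NRAS	Q61R
NRAS	G12D
BRAF	V600E
EGFR	L858R
EGFR	T790M
PIK3CA	E542K
PIK3CA	E545K
PIK3CA	H1047R
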
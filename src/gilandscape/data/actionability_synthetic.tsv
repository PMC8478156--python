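gene	rule_type	pattern
KRAS	protein_change	G12
KRAS	protein_change	G13
KRAS	protein_change	Q61
PIK3CA	protein_change	E542
PIK3CA	protein_change	E545
PIK3CA	protein_change	H1047R
BRAF	protein_change	V600E
BRAF	protein_change	G466V
BRAF	protein_change	L597R
KIT	class	inframe_indel
KIT	class	frameshift_indel
BRCA2	class	nonsense
BRCA2	class	stop_gain
BRCA2	class	frameshift_indel
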
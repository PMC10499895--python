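# Inverse-PCR control band sizes observed on unrearranged DNA.
# These are wet-lab reference values; `fusionbreak insilico-pcr` recomputes
# them from a user-supplied GRCh38 region FASTA (see scripts/fetch_reference.py).
forward	reverse	enzyme	size_bp
TCF3-F2	TCF3-R4	BamHI	3308
TCF3-F6	TCF3-R4	BamHI	2131
TCF3-F2	TCF3-R5	SphI	5026
TCF3-F6	TCF3-R5	SphI	3849
TCF3-F2	TaqI-R	TaqI	7567
TCF3-F6	TaqI-R	TaqI	6390
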
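# Restriction enzyme definitions used by the in-silico assay.
# cut_offset_top / cut_offset_bottom: number of bases from the 5' end of the
# recognition site to the cut on the top / bottom strand (0..len(site)).
# BamHI is shipped with its canonical recognition site GGATCC (the source
# protocol's "G|GACC" is a typographical truncation of G|GATCC).
name	recognition	cut_offset_top	cut_offset_bottom	note
SphI	GCATGC	5	1	GCATG|C, 4-nt 3' overhang
BamHI	GGATCC	1	5	G|GATCC, 4-nt 5' overhang
TaqI	TCGA	1	3	T|CGA, 2-nt 5' overhang
EcoRV	GATATC	3	3	blunt cutter, fails sticky-end screen
BstXI	CCANNNNNNTGG	8	4	degenerate site, fails non-degeneracy screen
NotI	GCGGCCGC	2	6	8-cutter, fails frequent-cutter screen
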
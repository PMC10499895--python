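# Long range-inverse PCR and multiplex long-range PCR oligonucleotides (5'->3').
# role: forward primers anneal to the plus strand; reverse/panel primers anneal
# so that their reverse complement occurs on the plus strand.
name	sequence	role
TCF3-F2	CTCCCTGACCTGTCTCGGCCTCCCGACT	forward
TCF3-F6	ACCTTGATTCTATCACTCCTAGGCCAGGGCA	forward
TCF3-F7	AGGAGGGTTTCAGGCAGAGGGCGCA	forward
TCF3-R4	GAAGGCCTGGGCTACGGAGGGGAACAGCT	reverse
TCF3-R5	CACAGGCCTCCATTCATGTCCCTTCCGCA	reverse
TaqI-R	AGGCCGTGGAGACCCCCGTCGTAGCT	reverse
PBX-long1	CCCGGGGTTGTGCTTCCTCCACCCTT	panel1
PBX-long2	TGCGCTCTCTCCCTCCCCCTCATCTCT	panel1
PBX-long3	ACGTGGTCCTGCGAGGAGCTCTTAGA	panel1
PBX-long4	TGCCCATGCAGCAGGTGACAAGGG	panel1
PBX1-long5	ACGAATCAGGCAGCTGTACAGAAAGCA	panel2
PBX1-long6	TCGGCCTCACCTAACTGACTTGCAGGT	panel2
PBX1-long7	AGCACCATCCTGAAGTTGCTCGGCT	panel2
PBX1-long8	TGCGGGAGGCTGGCAACATTGAGTC	panel2
PBX1-long9	ACACAGGTGCTACCTCTGCTCTGCCA	panel2
PBX1-long10	TCCAGCTACCTCATGGCTCGCTAGA	panel2
TCF3-qF	CAGGCAGACTTTCCAAGTACCTT	qpcr_forward
TCF3-FAM	CTATCACTCCTAGGCCAGGGCATCT	qpcr_probe
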
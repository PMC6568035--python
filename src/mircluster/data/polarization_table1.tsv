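# The 9 ethanol-responsive miRNAs associated with macrophage polarization
# (5 M1, 4 M2), with their published log2 fold changes and FDR.
mirna	label	logFC	FDR	sources
rno-miR-291a-5p	M2	1.008	0.08	B29;B30
rno-miR-125a-3p	M1	-0.65	0.07	B31
rno-miR-221-5p	M2	-0.73	0.12	B29;B30
rno-miR-100-5p	M2	-1.77	0	B29
rno-miR-214-3p	M1	-1.92	0.1	B31
rno-miR-455-5p	M1	-2.03	0.04	B31
rno-miR-152-5p	M2	-2.04	0.01	B30
rno-miR-143-3p	M1	-2.11	0.02	B30
rno-miR-199a-3p	M1	-2.31	0.01	B31
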
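# Static cross-species host-gene reference for the 13 rat miRNA clusters
# (plus the human let-7c/miR-99a counterpart of cluster 4), transcribed as
# published. '<' marks an antisense host; 'unknown'/'-' = not annotated.
# Shipped for reference only; no computation uses it.
cluster_id	rat_host	rat_chr	mouse_host	mouse_chr	human_host	human_chr	members
1	Spaca6	1	Spaca6	17	Spaca6	19	rno-miR-99b-5p,rno-miR-99b-3p,rno-miR-3596c,rno-let-7e-5p,rno-let-7e-3p,rno-miR-125a-5p,rno-miR-125a-3p
2	Nlrp12<	1	Nlrp12<	7	Nlrp12	19	rno-miR-294,rno-miR-293-3p,rno-miR-293-5p,rno-miR-291b,rno-miR-292-3p,rno-miR-292-5p,rno-miR-291a-3p,rno-miR-291a-5p,rno-miR-290
3	Nr6a1<	3	Nr6A1os	2	MiR181A2HG	9	rno-miR-181a-5p,rno-miR-181a-2-3p,rno-miR-181b-5p,rno-miR-181b-2-3p
4	unknown	7	Lncppara	15	-	-	rno-let-7c-5p,rno-let-7c-2-3p,rno-let-7b-5p,rno-let-7b-3p
4b	unknown	11	Mir99aHG	26	MiR99aHG	21	rno-miR-99a-5p,rno-miR-99a-3p,rno-let-7c-1-3p
5	Lnc215	8	3110039I08Rik	9	miR100HG	11	rno-miR-100-5p,rno-miR-100-3p,rno-miR-3596a,rno-let-7a-5p,rno-let-7a-2-3p,rno-miR-125b-5p,rno-miR-125b-1-3p
6	RGD1308134<	10	unknown	11	miR497HG	17	rno-miR-497-5p,rno-miR-497-3p,rno-miR-195-5p,rno-miR-195-3p
7	unknown	13	unknown	1	miR181A1HG	1	rno-miR-181a-5p,rno-miR-3570,rno-miR-181a-1-3p,rno-miR-181b-5p,rno-miR-181b-1-3p
8	Dnm3<	13	Dnm3<	1	NR_103486.1/Dnm3<	1	rno-miR-199a-5p,rno-miR-199a-3p,rno-miR-214-5p,rno-miR-3120,rno-miR-214-3p
9	Npepo	17	2010111I01Rik	13	C9orf3	9	rno-miR-23b-5p,rno-miR-23b-3p,rno-miR-27b-5p,rno-miR-27b-3p,rno-miR-3074,rno-miR-24-1-5p,rno-miR-24-3p
10	unknown	18	CARMN	18	CARMN	5	rno-miR-145-3p,rno-miR-145-5p,rno-miR-143-3p,rno-miR-143-5p
11	unknown	X	unknown	X	miR222HG	X	rno-miR-222-5p,rno-miR-222-3p,rno-miR-221-5p,rno-miR-221-3p
12	unknown	X	unknown	X	LOC105373347<	X	rno-miR-509-5p,rno-miR-509-3p,rno-miR-547-5p,rno-miR-547-3p,rno-miR-201-5p,rno-miR-201-3p,rno-miR-3585-5p,rno-miR-3585-3p
13	unknown	X	RikencDNA	X	miR503HG	X	rno-miR-322,rno-miR-322*,rno-miR-503,rno-miR-503*,rno-miR-351,rno-miR-351*,rno-miR-542-5p,rno-miR-542-3p,rno-miR-450a-5p,rno-miR-450a-3p
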
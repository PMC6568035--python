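# Published rat miRNA cluster table: 13 genomic clusters (>= 4 mature miRNAs
# within 1 Mb), their spans, strand, polarization call, DE direction, host
# gene ('antisense' = overlapping gene on the opposite strand) and members.
# de_members are the cluster members that were differentially expressed.
cluster_id	chrom	first	last	strand	polarization	de_direction	host_gene	host_relation	members	de_members
1	1	59704222	59704900	+	M1	down	Spaca6	sense-intronic	rno-miR-99b-5p,rno-miR-99b-3p,rno-miR-3596c,rno-let-7e-5p,rno-let-7e-3p,rno-miR-125a-5p,rno-miR-125a-3p	rno-miR-125a-3p
2	1	64536787	64538773	-	M2	up	Nlrp12	antisense	rno-miR-294,rno-miR-293-3p,rno-miR-293-5p,rno-miR-291b,rno-miR-292-3p,rno-miR-292-5p,rno-miR-291a-3p,rno-miR-291a-5p,rno-miR-290	rno-miR-291a-5p
3	3	23150390	23151528	+	none	down	Nr6a1	antisense	rno-miR-181a-5p,rno-miR-181a-2-3p,rno-miR-181b-5p,rno-miR-181b-2-3p	rno-miR-181a-2-3p
4	7	126590225	126590708	+	none	down			rno-let-7c-5p,rno-let-7c-2-3p,rno-let-7b-5p,rno-let-7b-3p	rno-let-7b-3p
5	8	45746960	45798335	+	M2	down	Lnc215	sense-intronic	rno-miR-100-5p,rno-miR-100-3p,rno-miR-3596a,rno-let-7a-5p,rno-let-7a-2-3p,rno-miR-125b-5p,rno-miR-125b-1-3p	rno-miR-100-5p
6	10	56844978	56845375	+	none	down	RGD1308134	antisense	rno-miR-497-5p,rno-miR-497-3p,rno-miR-195-5p,rno-miR-195-3p	rno-miR-497-5p,rno-miR-195-5p,rno-miR-195-3p
7	13	54952756	54952998	+	none	down			rno-miR-181a-5p,rno-miR-3570,rno-miR-181a-1-3p,rno-miR-181b-5p,rno-miR-181b-1-3p	rno-miR-181b-1-3p
8	13	80125517	80130995	+	M1	down	Dnm3	antisense	rno-miR-199a-5p,rno-miR-199a-3p,rno-miR-214-5p,rno-miR-3120,rno-miR-214-3p	rno-miR-199a-5p,rno-miR-199a-3p,rno-miR-214-5p,rno-miR-3120,rno-miR-214-3p
9	17	823242	824032	+	none	down	Npepo	sense-intronic	rno-miR-23b-5p,rno-miR-23b-3p,rno-miR-27b-5p,rno-miR-27b-3p,rno-miR-3074,rno-miR-24-1-5p,rno-miR-24-3p	rno-miR-23b-3p,rno-miR-27b-5p,rno-miR-27b-3p
10	18	56969921	56971352	-	M2	down			rno-miR-145-3p,rno-miR-145-5p,rno-miR-143-3p,rno-miR-143-5p	rno-miR-145-5p,rno-miR-143-3p
11	X	3683940	3684566	+	M2	down			rno-miR-222-5p,rno-miR-222-3p,rno-miR-221-5p,rno-miR-221-3p	rno-miR-221-5p
12	X	155317221	155344260	+	none	down			rno-miR-509-5p,rno-miR-509-3p,rno-miR-547-5p,rno-miR-547-3p,rno-miR-201-5p,rno-miR-201-3p,rno-miR-3585-5p,rno-miR-3585-3p	rno-miR-3585-3p
13	X	158148183	158153448	+	none	down			rno-miR-322,rno-miR-322*,rno-miR-503,rno-miR-503*,rno-miR-351,rno-miR-351*,rno-miR-542-5p,rno-miR-542-3p,rno-miR-450a-5p,rno-miR-450a-3p	rno-miR-322*,rno-miR-542-3p
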
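# SYNTHETIC stand-in for the full edgeR differential-expression table
# (ethanol vs pair-fed, LPS as covariate). The 9 polarization-table rows
# carry their published logFC/FDR; all other values are synthetic but
# preserve the published structure: 40 miRNAs at FDR < 0.2 (2 up, 38
# down), 23 of them inside the 13 genomic clusters.
GeneID	logFC	LR	PValue	FDR
rno-miR-291a-5p	1.008	4.598	0.032	0.08
rno-miR-125a-3p	-0.65	4.828	0.028	0.07
rno-miR-221-5p	-0.73	3.91	0.048	0.12
rno-miR-100-5p	-1.77	23.928	1e-06	0.0
rno-miR-214-3p	-1.92	4.218	0.04	0.1
rno-miR-455-5p	-2.03	5.803	0.016	0.04
rno-miR-152-5p	-2.04	8.284	0.004	0.01
rno-miR-143-3p	-2.11	7.033	0.008	0.02
rno-miR-199a-3p	-2.31	8.284	0.004	0.01
rno-miR-181a-2-3p	-1.174	3.219	0.0728	0.182
rno-let-7b-3p	-1.904	3.828	0.0504	0.126
rno-miR-497-5p	-1.014	3.571	0.0588	0.147
rno-miR-195-5p	-2.274	3.38	0.066	0.165
rno-miR-195-3p	-1.388	6.433	0.0112	0.028
rno-miR-181b-1-3p	-1.081	4.93	0.0264	0.066
rno-miR-199a-5p	-1.8	4.878	0.0272	0.068
rno-miR-214-5p	-1.951	3.688	0.0548	0.137
rno-miR-3120	-0.845	3.237	0.072	0.18
rno-miR-23b-3p	-1.962	3.953	0.0468	0.117
rno-miR-27b-5p	-1.153	3.7	0.0544	0.136
rno-miR-27b-3p	-2.37	4.184	0.0408	0.102
rno-miR-145-5p	-2.174	6.863	0.0088	0.022
rno-miR-3585-3p	-1.091	3.219	0.0728	0.182
rno-miR-322*	-0.726	3.924	0.0476	0.119
rno-miR-542-3p	-2.307	7.434	0.0064	0.016
syn-miR-d01	0.9	3.594	0.058	0.145
syn-miR-d02	-1.32	6.253	0.0124	0.031
syn-miR-d03	-1.465	3.311	0.0688	0.172
syn-miR-d04	-1.939	4.556	0.0328	0.082
syn-miR-d05	-2.301	7.809	0.0052	0.013
syn-miR-d06	-0.821	4.62	0.0316	0.079
syn-miR-d07	-2.375	3.869	0.0492	0.123
syn-miR-d08	-1.015	3.462	0.0628	0.157
syn-miR-d09	-1.876	4.184	0.0408	0.102
syn-miR-d10	-0.862	3.148	0.076	0.19
syn-miR-d11	-2.295	4.515	0.0336	0.084
syn-miR-d12	-1.97	3.183	0.0744	0.186
syn-miR-d13	-1.423	3.64	0.0564	0.141
syn-miR-d14	-1.338	3.841	0.05	0.125
syn-miR-d15	-0.726	4.515	0.0336	0.084
rno-miR-99b-5p	-0.256	0.536	0.464	0.58
rno-miR-99b-3p	0.123	0.139	0.7096	0.887
rno-miR-3596c	0.919	0.394	0.5304	0.663
rno-let-7e-5p	-1.066	0.07	0.7912	0.989
rno-let-7e-3p	-0.307	0.745	0.388	0.485
rno-miR-125a-5p	0.47	0.484	0.4864	0.608
rno-miR-294	0.265	0.465	0.4952	0.619
rno-miR-293-3p	-0.726	0.135	0.7128	0.891
rno-miR-293-5p	-0.054	1.438	0.2304	0.288
rno-miR-291b	-0.422	0.843	0.3584	0.448
rno-miR-292-3p	-0.335	1.727	0.1888	0.236
rno-miR-292-5p	0.157	0.628	0.428	0.535
rno-miR-291a-3p	-0.086	1.015	0.3136	0.392
rno-miR-290	-0.714	1.778	0.1824	0.228
rno-miR-181a-5p	-0.354	0.419	0.5176	0.647
rno-miR-181b-5p	0.265	0.135	0.7128	0.891
rno-miR-181b-2-3p	0.257	0.866	0.352	0.44
rno-let-7c-5p	0.182	1.494	0.2216	0.277
rno-let-7c-2-3p	-0.194	0.226	0.6344	0.793
rno-let-7b-5p	-0.465	0.247	0.6192	0.774
rno-miR-100-3p	0.534	1.453	0.228	0.285
rno-miR-3596a	0.552	0.501	0.4792	0.599
rno-let-7a-5p	-0.569	0.976	0.3232	0.404
rno-let-7a-2-3p	-0.036	1.129	0.288	0.36
rno-miR-125b-5p	0.448	1.339	0.2472	0.309
rno-miR-125b-1-3p	-0.15	1.672	0.196	0.245
rno-miR-497-3p	0.026	1.239	0.2656	0.332
rno-miR-3570	-0.279	0.678	0.4104	0.513
rno-miR-181a-1-3p	0.823	0.81	0.368	0.46
rno-miR-23b-5p	0.02	0.414	0.52	0.65
rno-miR-3074	-0.642	0.816	0.3664	0.458
rno-miR-24-1-5p	0.138	0.4	0.5272	0.659
rno-miR-24-3p	-0.106	0.558	0.4552	0.569
rno-miR-145-3p	-0.355	0.776	0.3784	0.473
rno-miR-143-5p	0.505	1.032	0.3096	0.387
rno-miR-222-5p	-0.119	0.074	0.7856	0.982
rno-miR-222-3p	0.268	0.256	0.6128	0.766
rno-miR-221-3p	-0.217	0.406	0.524	0.655
rno-miR-509-5p	-0.182	1.879	0.1704	0.213
rno-miR-509-3p	-0.086	0.383	0.536	0.67
rno-miR-547-5p	-0.207	0.351	0.5536	0.692
rno-miR-547-3p	0.223	0.224	0.636	0.795
rno-miR-201-5p	-0.308	0.1	0.752	0.94
rno-miR-201-3p	-0.203	0.205	0.6504	0.813
rno-miR-3585-5p	-0.355	0.432	0.5112	0.639
rno-miR-322	0.48	0.16	0.6888	0.861
rno-miR-503	-0.844	1.818	0.1776	0.222
rno-miR-503*	0.153	0.536	0.464	0.58
rno-miR-351	0.522	0.385	0.5352	0.669
rno-miR-351*	0.217	0.474	0.4912	0.614
rno-miR-542-5p	-0.436	0.082	0.7752	0.969
rno-miR-450a-5p	-0.004	0.345	0.5568	0.696
rno-miR-450a-3p	1.138	0.357	0.5504	0.688
syn-miR-n01	0.245	0.3	0.584	0.73
syn-miR-n02	-0.412	0.221	0.6384	0.798
syn-miR-n03	0.615	0.236	0.6272	0.784
syn-miR-n04	0.006	0.155	0.6936	0.867
syn-miR-n05	0.001	0.598	0.4392	0.549
syn-miR-n06	-0.402	0.228	0.6328	0.791
syn-miR-n07	-0.171	0.508	0.476	0.595
syn-miR-n08	-0.536	1.666	0.1968	0.246
syn-miR-n09	0.281	0.12	0.7288	0.911
syn-miR-n10	-1.013	0.341	0.5592	0.699
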
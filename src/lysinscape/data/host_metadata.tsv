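genus	gram	outer_architecture	chemotype	is_genus	genomes_retrieved	genes_detected	genes_curated	pf_hits
Achromobacter	G-	diderm-LPS	A1γ	1	36	32	10	13
Acidovorax	G-	diderm-LPS	A1γ	1	3	4	2	2
Acinetobacter	G-	diderm-LPS	A1γ	1	139	152	50	57
Aeromonas	G-	diderm-LPS	A1γ	1	95	77	26	27
Bacteroides	G-	diderm-LPS	A1γ	1	5	6	3	3
Burkholderia	G-	diderm-LPS	A1γ	1	72	61	27	36
Caulobacter	G-	diderm-LPS	A1γ	1	42	58	17	17
Cellulophaga	G-	diderm-LPS	A1γ	1	52	38	9	9
Cronobacter	G-	diderm-LPS	A1γ	1	45	64	24	26
Enterobacter	G-	diderm-LPS	A1γ	1			1	1
Enterobacteria	G-	diderm-LPS	A1γ	0	797	300	3	3
Enterovibrio	G-	diderm-LPS	A1γ	1			2	2
Escherichia	G-	diderm-LPS	A1γ	1	684	745	211	231
Fusobacterium	G-	diderm-LPS	A1γ	1	4	3	3	3
Klebsiella	G-	diderm-LPS	A1γ	1	266	259	67	71
Microcystis	G-	diderm-LPS	A1γ	1	8	8	5	5
Pseudomonas	G-	diderm-LPS	A1γ	1	625	485	89	98
Ralstonia	G-	diderm-LPS	A1γ	1	68	21	14	15
Salmonella	G-	diderm-LPS	A1γ	1	414	444	90	93
Serratia	G-	diderm-LPS	A1γ	1	31	40	13	16
Shewanella	G-	diderm-LPS	A1γ	1			1	1
Shigella	G-	diderm-LPS	A1γ	1			3	3
Sphingobium	G-	diderm-LPS	A1γ	1	2	2	1	2
Sphingomonas	G-	diderm-glycosphingolipid	A1γ	1	7	2	1	1
Stenotrophomonas	G-	diderm-LPS	A1γ	1	28	25	6	8
Vibrio	G-	diderm-LPS	A1γ	1	578	225	76	85
Yersinia	G-	diderm-LPS	A1γ	1	70	62	16	16
Arthrobacter	G+	monoderm	A3α	1	316	400	103	161
Bacillus	G+	monoderm	A1α	1	348	400	150	286
Bifidobacterium	G+	monoderm	A4α	1	10	2	1	1
Clostridioides	G+	monoderm	A1γ	1			23	25
Clostridium	G+	monoderm	A1γ	1	109	174	30	43
Corynebacterium	G+	diderm-mycolic	A1γ	1	40	30	16	24
Cutibacterium	G+	monoderm	A3γ	1			65	65
Enterococcus	G+	monoderm	A3α	1	127	150	50	77
Lacticaseibacillus	G+	monoderm	A4α	1			13	28
Lactiplantibacillus	G+	monoderm	A4α	1			18	42
Lactobacillus	G+	monoderm	A4α	1	105	133	22	41
Lactococcus	G+	monoderm	A3α	1	388	376	121	144
Leuconostoc	G+	monoderm	A3α	1	35	45	11	16
Levilactobacillus	G+	monoderm	A4α	1			9	14
Limosilactobacillus	G+	monoderm	A4α	1			6	14
Listeria	G+	monoderm	A1γ	1	75	87	17	32
Mycobacterium	G+	diderm-mycolic	A1γ	1	1990	3596	299	374
Propionibacterium	G+	monoderm	A3γ	1	202	214	5	8
Rhodococcus	G+	diderm-mycolic	A1γ	1	70	83	31	70
Staphylococcus	G+	monoderm	A3α	1	349	456	79	155
Streptococcus	G+	monoderm	A3α	1	1064	739	246	688
Streptomyces	G+	monoderm	A3γ	1	240	208	97	151
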
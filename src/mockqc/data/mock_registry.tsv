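strain_id	species_name	genome_size_bp	gc_percent	n_16s	gram_type	abundance_dna_pct	abundance_cell_pct
NBRC 113350	Bacteroides uniformis	4989532	46.2	4	-	4.7	5.6
NBRC 113351	Blautia sp.	6247046	46.7	5	+	4.5	5.6
NBRC 113352	Enterocloster clostridioformis	5687315	48.9	5	+	5.3	5.6
NBRC 113806	Parabacteroides distasonis	5179960	45.0	7	-	4.8	5.6
NBRC 13719	Bacillus subtilis subsp. subtilis	4295305	43.3	10	+	5.2	5.6
NBRC 13955	Streptococcus mutans	2018796	36.9	5	+	6.9	5.6
NBRC 14164	Pseudomonas putida	6156701	62.3	7	-	3.9	5.6
NBRC 3202	Lactobacillus delbrueckii subsp. delbrueckii	1910306	50.1	8	+	3.6	5.6
NBRC 3301	Escherichia coli	4755096	50.8	7	-	5.6	5.6
NBRC 113805	Flavonifractor plautii	4277038	60.4	3	+	3.7	5.6
NBRC 113846	Staphylococcus epidermidis	2520735	32.2	6	+	4.8	5.6
NBRC 113869	Cutibacterium acnes subsp. acnes	2560907	60.0	3	+	5.0	5.6
NBRC 114370	Bifidobacterium longum	2594022	60.1	5	+	5.7	5.6
NBRC 114412	Anaerostipes caccae	3284789	44.5	4	+-	5.3	5.6
NBRC 114413	Ruminococcus gnavus	3757469	42.5	5	+	5.6	5.6
NBRC 114414	Megasphaera massiliensis	2610024	50.6	7	-	4.8	0
NBRC 114415	Megamonas funiformis	2464533	31.5	6	-	3.7	0
NBRC 114504	Collinsella aerofaciens	2278612	60.3	5	+	6.2	5.6
NBRC 114494	Bifidobacterium longum subsp. longum	2534372	60.1	4	+	4.7	5.6
NBRC 114322	Akkermansia muciniphila	2788458	55.7	3	-	6.0	5.6
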
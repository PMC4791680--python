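locus	chromosome	motif	motif_repeats	primer_f	primer_r	n	size_min	size_max	n_alleles	he	ho	p_hwe	hwe_deviation	linked_gene
1A720	1	AAAG	14	GATAGACATCTCAGTGCCAAAC	AGTCCAAAGAGAATCAGAGTTC	22	335	345	4	0.354	0.318	0.641		Bone morphogenetic protein receptor type-2 precursor
2A1340	2	AAAG	15	TTGGAGAGGCAGAATTAACTTG	CATGTAAATGTGAGCAAACCAC	17	296	321	7	0.713	0.529	0.025	*	Metallophosphoesterase domain containing 2
2A2910	2	AAAC	8	CATCAATTTATCCTCCACCCTC	ATTTGTAGCTTGGGTTTGTCTC	24	318	335	5	0.696	0.708	0.974
3A2393	3	AGAT	8	CCCAGAAACTTAGAAGCTAGTG	CATTAGAGTGTCACGGAAGAG	21	244	260	8	0.828	0.667	0.172		Cysteine conjugate-beta lyase 2
4A2131	4	ACTC	10	ATTTCCATTCCAGAATCTCCAC	TTGTTTAAAGGTGCAAGGTTTG	23	134	156	9	0.831	0.783	0.802		Transmembrane protein 246
5A672	5	AGAT	12	AAAGGTTTACAACTCCATACCC	GAAGGAGTAAGATGCACAGAAC	24	230	346	5	0.751	0.75	0.839
5B59	5	AAAG	21	ATGCTGGTATTGTGTAGGATTG	TTAGTGTAGAGGAATGAGAGGC	24	186	207	17	0.918	0.833	0.435
6A496	6	AGAT	15	GTAAAGTTGTGCAATGTCAGC	TATAATGTCCTAGCTCTGTAGG	23	437	457	6	0.82	0.913	0.941		Neurexophilin 1
6A565	6	AGAT	18	AGTTAATTCAGTGCTTGTTGGG	ATCTGATCTCCTCTTCTGTCAG	24	246	318	9	0.862	0.708	0.028	*
8A401	8	AAAC	8	TCAACACTTTCGAGGTTTAGTC	CTTTGCTTTGATTGTGACCATG	24	352	368	4	0.574	0.5	0.725		Coiled-coil domain containing 130
8A1226	8	AGAT	12	TCATTCCATTTCCAACTCAGAC	CTTTGCTTTGATTGTGACCATG	24	418	422	2	0.422	0.417	1
8A472	8	ACAT	9	AAAGGGAGGAGGAAGAAAGAAC	CCATTAGCACCATCTCTATTCG	22	349	403	19	0.947	0.864	0.012	*
9A1141	9	AACT	12	GATCTGGTCTGAGTTGTCTG	CCATTAGCACCATCTCTATTCG	21	227	235	3	0.528	0.238	0.007	*	Centrosomal protein 70
9B878	9	AGAT	9	AAGAGACAGTATTGAAAGCATG	AGCTGAATTTACTCCAAGCATC	24	407	439	9	0.87	0.75	0.422		Olfactory receptor 904
10B1562	10	AGAT	11	CAGCACTAAACCTAACTACACC	AGCTGAATTTACTCCAAGCATC	22	427	428	2	0.304	0.182	0.106		Transmembrane and tetratricopeptide repeat containing protein 2
11A2041	11	AATG	8	TCTAAATTCTTGATGCACCTGG	AGCTGAATTTACTCCAAGCATC	9	348	372	7	0.81	0.667	0.1563
12A1292	12	AGAT	9	TCATCTATTGATTGATCCACCC	CAGATATAGACACGGAGGTAGG	20	272	315	14	0.933	0.9	0.540		A kinase (PRKA) anchor protein 6
12A1851	12	ACAT	10	CCACCCTTCCATCTATTCATTC	CAGATATAGACACGGAGGTAGG	21	329	369	10	0.835	0.381	0	*	Family with sequence similarity 181, member A
14A594	14	ACAG	8	CCTATGGAAGCTTTGTGAGTTG	ATAATTCAACCAAACCGTGTCC	22	445	471	12	0.915	0.909	0.927		Potassium large conductance calcium-activated channel, subfamily M, alpha member 1
15B141	15	AAGG	10	CAAGAACAGGAGAAGAGTCAAG	TATATTCAACTGAGTCACTGCC	21	410	419	3	0.354	0.333	1		Zinc finger protein 706
15B636	15	AGAT	13	CACAAGTGTAAGGGTATTGG	CTAGGGACAATGAACTGACATG	24	310	314	4	0.301	0.25	0.093		Ubiquitin protein ligase E3 component n-recognin 5
17A410	17	AAAC	9	ACATATCTAGTTTCAAGCCAGC	CAAGTCTCATTGGGTCTATCTG	19	172	181	7	0.858	0.842	0.410		Meiosis-specific with OB domains
17A501	17	ACAT	10	AGAGAATACAATATGGCACTGC	CAAGTCTCATTGGGTCTATCTG	18	348	371	9	0.867	0.889	0.536		Regulator of microtubule dynamics 2
18A352	18	AAGG	12	CCAAATTTAAAGGGAGGCAATG	CAAGTCTCATTGGGTCTATCTG	24	277	286	2	0.254	0.042	0.001	*	Mucosa associated lymphoid tissue lymphoma translocation gene 1
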
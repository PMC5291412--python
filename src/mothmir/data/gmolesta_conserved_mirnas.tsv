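mirna	sequence	length	seed	gc_pct	free_energy	reads
bmo-miR-10-5p_L+1	TACCCTGTAGATCCGAATTTGT	22	ACCCTGT	44.20	-37.10	338584
mse-miR-8	TAATACTGTCAGGTAAAGATGTC	23	AATACTG	50.00	-40.50	330445
bmo-miR-276-3p	TAGGAACTTCATACCGTGCTCT	22	AGGAACT	44.90	-38	125388
bmo-miR-14-3p_R+1	TCAGTCTTTTTCTCTCTCCTAT	22	CAGTCTT	40.00	-31.70	55077
bmo-miR-281-5p_R+1	AAGAGAGCTATCCGTCGACAGTA	23	AGAGAGC	39.80	-39.60	29116
bmo-miR-11-3p_1ss11AG	CATCACAGTCGGAGTTCTAGCT	22	ATCACAG	56.50	-38.80	27252
bmo-miR-279d-3p	TGACTAGATTTTCACTTATCCT	22	GACTAGA	39.40	-22.60	26764
bmo-miR-31-5p_L+1R+1_1ss9AT	AGGCAAGATGTCGGCATAGCTGA	23	GGCAAGA	57.00	-48.20	25425
bmo-mir-6497-p5	GGAATAAGGATTGGCTCTGAGGAC	24	GAATAAG	64.80	-36.90	24686
mse-miR-263a_R-1	AATGGCACTGGAAGAATTCACGG	23	ATGGCAC	50.00	-34.10	21512
bmo-miR-9a-5p	TCTTTGGTTATCTAGCTGTATGA	23	CTTTGGT	40.40	-33.30	21174
mse-miR-6094	TATTCGAGACCTCTGCTGATCCT	23	ATTCGAG	51.30	-51.40	19051
bmo-miR-2b-3p_1ss22GC	TATCACAGCCAGCTTTGTTGACT	23	ATCACAG	46.20	-48.30	18960
bmo-miR-263a-5p_R+4	AATGGCACTGGAAGAATTCACGGGA	25	ATGGCAC	51.50	-40.50	14803
bmo-miR-71-3p_L-1R+1	TCTCACTACCTTGTCTTTCATG	22	CTCACTA	47.70	-44.50	13455
mse-miR-277	TAAATGCACTATCTGGTACGACA	23	AAATGCA	51.60	-39.50	8369
bmo-miR-277-3p	TAAATGCACTATCTGGTACGACA	23	AAATGCA	51.70	-56.50	8369
bmo-miR-279b-3p_R-1	TGACTAGATCTACACTCATTG	21	GACTAGA	40.50	-47.60	7814.50
bmo-miR-282-5p_L-3R-2	TAGCCTCTCCTTGGCTTTGTCT	22	AGCCTCT	46.00	-37.90	6909
bmo-miR-750-3p_R+2	CCAGATCTATCTTTCCAGCTCA	22	CAGATCT	48.80	-33	6646
pxy-miR-274	TTTGTGACCGTCACTAACGGGCA	23	TTGTGAC	43.40	-29.50	6383
bmo-miR-10-3p	CAAATTCGGTTCTAGAGAGGTTT	23	AAATTCG	44.20	-37.10	5036
bmo-miR-31-5p_L+1R-2_1ss9AT	AGGCAAGATGTCGGCATAGC	20	GGCAAGA	57.00	-48.20	4591
bmo-let-7-5p	TGAGGTAGTAGGTTGTATAGT	21	GAGGTAG	52.00	-50.90	4349
mse-miR-278	TCGGTGGGATCTTCGTCCGTTT	22	CGGTGGG	54.30	-39	4269
bmo-miR-281-3p_L-2R+2	TGTCATGGAGTTGCTCTCTTTA	22	GTCATGG	39.80	-39.60	4260
bmo-miR-252-5p	CTAAGTACTAGTGCCGCAGGAG	22	TAAGTAC	37.20	-33.10	4031
dme-miR-10-5p_L+1_1ss23TA	TACCCTGTAGATCCGAATTTGTA	23	ACCCTGT	47.60	-48.60	3798
bmo-miR-1175-3p_R-2	TGAGATTCAACTCCTCCAACTT	22	GAGATTC	38.20	-23.50	3749
mse-mir-8-p5	CATCTTACCGGGCAGCATTAGA	22	ATCTTAC	50.00	-40.50	3279
bmo-miR-7-5p_R+1	TGGAAGACTAGTGATTTTGTTGTT	24	GGAAGAC	34.70	-24.30	3037
bmo-mir-6497-p3	GCGTGTCGGGTTTGGACGGGAAG	23	CGTGTCG	64.80	-36.90	2985
dme-miR-8-3p_R+1	TAATACTGTCAGGTAAAGATGTCC	24	AATACTG	52.50	-51.30	2914
bmo-miR-133	TTGGTCCCCTTCAACCAGCTGT	22	TGGTCCC	42.70	-39.90	2828
bmo-miR-305-5p_R+1	ATTGTACTTCATCAGGTGCTCTGG	24	TTGTACT	56.80	-48.30	2595
bmo-miR-263a-5p_R+5	AATGGCACTGGAAGAATTCACGGGAA	26	ATGGCAC	45.30	-34	2590
bmo-miR-279c-3p_R+1	TGACTAGATCCATACTCGTCTGC	23	GACTAGA	40.20	-36.90	2469.50
bmo-miR-317-3p_L-2	TGAACACAGCTGGTGGTATC	20	GAACACA	57.00	-41.50	2318
bmo-miR-2765	TGGTAACTCCACCACCGTTGGC	22	GGTAACT	57.60	-59.80	2154
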
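mirna	sequence	length	seed	gc_pct	free_energy	reads
gmo-miR-PC-5p-15_50867	CGCAATATATTGAATGGGCCTG	22	GCAATAT	48.40	-33.10	127819
gmo-miR-PC-3p-598_1629	ACCAAACTTGATCATTTAGAGGAAGT	26	CCAAACT	49.40	-57.50	17872
gmo-miR-PC-3p-674_1493	ACCCTGTTGAGCTTGACTCTAGTCT	25	CCCTGTT	50.30	-53.20	17424
gmo-miR-PC-5p-1258_867	TACCGATTGAATGATTTAGTGAGGTC	26	ACCGATT	49.40	-57.50	14307
gmo-miR-PC-5p-1018_1028	GACCCTGTTGAGCTTGACTCTAGTCT	26	ACCCTGT	50.30	-53.20	9152
gmo-miR-PC-5p-671_1474	CGGGAGGAGGAGTGTTAAACT	21	GGGAGGA	65.20	-89.30	1593
gmo-miR-PC-5p-1276_891	CCATCAAAGTCGGTTTGTTATA	22	CATCAAA	38.00	-30.90	1050
gmo-miR-PC-3p-1433_822	GTGAATCGTATGTAAAAGT	19	TGAATCG	25.20	-20.20	863
gmo-miR-PC-3p-4029_320	CATCACAGTCGGAGTTCTAGCTT	23	ATCACAG	56.50	-38.80	323
gmo-miR-PC-3p-16268_91	GCCCCATTCAATATACTGCCGA	22	CCCCATT	48.40	-33.10	164
gmo-miR-PC-5p-35148_41	TTGTAGAATTGGCGAGAAATTAGAGC	26	TGTAGAA	52.50	-34.10	159
gmo-miR-PC-3p-36514_40	TGGTGTACCGAACTTTTTGAGT	22	GGTGTAC	37.30	-31.20	121
gmo-miR-PC-3p-20051_73	TAAGCAATTCTATAGGGTTTG	21	AAGCAAT	28.10	-26.70	102
gmo-miR-PC-5p-94853_15	TTAGCTGTACATCGGTGGACCT	22	TAGCTGT	43.60	-55.50	97
gmo-miR-PC-5p-130153_12	ACTCAAAAAGTTCGGTACACC	21	CTCAAAA	38.10	-54.60	72.50
gmo-miR-PC-5p-89338_18	AATGGGTATGCATCTAGTGGC	21	ATGGGTA	40.50	-47.60	46
gmo-miR-PC-5p-82222_20	TACTCAAATAGTTCGGTACACC	22	ACTCAAA	37.30	-31.20	39.50
gmo-miR-PC-5p-83411_19	ATCCTACCGGCTGCGCCA	18	TCCTACC	53.60	-16.90	38
gmo-miR-PC-3p-217431_8	TGGTGTACCGAACTATTTGACT	22	GGTGTAC	38.10	-54.60	35.50
gmo-miR-PC-5p-66427_22	TTATACATATTTGTAGAATTGTAGCT	26	TATACAT	30.20	-41.70	35
gmo-miR-PC-5p-193418_8	TTGGAACAGAGCTGAATTTCATTTGT	26	TGGAACA	29.70	-30.20	26
gmo-miR-PC-5p-93171_18	ATTAGAATCAGTACGCTTTGTC	22	TTAGAAT	46.40	-36.40	24
gmo-miR-PC-5p-323567_7	GTCACAAATATCGGAACAACGCCT	24	TCACAAA	45.50	-66.10	20
gmo-miR-PC-3p-803068_3	NCGTTTTGACGATCGCAAAATG	22	CGTTTTG	44.00	-33.90	20
gmo-miR-PC-5p-113242_14	TTTAAGTACGTTTTGACCGGCT	22	TTAAGTA	44.90	-36.60	18
gmo-miR-PC-3p-146760_10	CAGATGGTAAACTCGATACT	20	AGATGGT	40.70	-35	17
gmo-miR-PC-5p-234779_7	TCACAAATATCTGAACATGCACT	23	CACAAAT	40.70	-44.20	16
gmo-miR-PC-3p-108996_14	TTCCTTCGTAGACTAAAATGGTAGTT	26	TCCTTCG	28.40	-19.70	16
gmo-miR-PC-5p-237240_7	GAGGTGGTCATAAATATCGGAACATC	26	AGGTGGT	45.00	-68.80	16
gmo-miR-PC-5p-139696_12	TCACAAATATCGGAACAACGCCT	23	CACAAAT	40.20	-28.30	15
gmo-miR-PC-5p-272779_7	AAAAGGGACCTTATTGTCGATGGCGC	26	AAAGGGA	43.90	-43.30	15
gmo-miR-PC-5p-399520_7	TGGACAAACATTGCTTTACGGGC	23	GGACAAA	52.40	-22.10	13
gmo-miR-PC-5p-390898_5	TTAGCTGTACATTAGTGGACCT	22	TAGCTGT	44.00	-58.80	13
gmo-miR-PC-3p-180380_9	ATCCTGTGGAACATCGGATTTGACT	25	TCCTGTG	58.00	-40.80	13
gmo-miR-PC-3p-478770_4	ACCATGTAGAATTGGAAAACCT	22	CCATGTA	38.50	-47.30	12
gmo-miR-PC-3p-292016_6	TGACACGCTAGCAACTTCTGCAGC	24	GACACGC	45.80	-42.30	12
gmo-miR-PC-3p-160035_12	CATGAATATGGTTTTTCCCC	20	ATGAATA	41.60	-22.70	12
gmo-miR-PC-5p-124799_12	TTGTGATGTGATAGTTGAAGTTGCC	25	TGTGATG	30.90	-23.50	12
gmo-miR-PC-5p-250424_7	TGACTATATATCGGAAGATGAGCAGG	26	GACTATA	44.00	-24	11
gmo-miR-PC-5p-654402_3	CAAGATGTCGGCATAGCTGATTT	23	AAGATGT	50.80	-25.90	11
gmo-miR-PC-3p-457779_7	TTCACTACTGAACAGAGGCCT	21	TCACTAC	54.40	-40.30	11
gmo-miR-PC-5p-150358_10	TACCGGTATCATTTGTATGTTC	22	ACCGGTA	40.00	-28.20	11
gmo-miR-PC-3p-629556_3	TAAGGTCCACCAATGTACAGCT	22	AAGGTCC	42.60	-46.50	11
gmo-miR-PC-5p-796447_3	ATTTCAAATGTCGTAAGTCGCA	22	TTTCAAA	36.70	-47	10
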
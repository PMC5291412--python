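distance_bp	cluster_id	member	reads
50000	1	bmo-miR-iab-4-3p_L-3R+1	10
50000	1	bmo-miR-iab-4-5p	59
50000	1	bmo-miR-iab-8_R+2	20
50000	2	bmo-miR-34-5p_R+1	1573
50000	2	bmo-miR-277-3p	8369
50000	2	bmo-miR-277-5p_L-1R+1	18.5
50000	2	bmo-miR-317-5p	22
50000	3	gmo-miR-PC-3p-1153688_2	2
50000	3	mse-mir-278-p5	36
50000	4	gmo-miR-PC-3p-674_1493	17424
50000	4	gmo-miR-PC-5p-1018_1028	9152
50000	4	bmo-mir-6497-p3	2985
50000	4	bmo-mir-6497-p5	24686
50000	4	gmo-miR-PC-5p-1258_867	14307
50000	5	bmo-miR-10-3p	5036
50000	5	bmo-miR-10-5p_L+1	338584
50000	5	dme-miR-10-5p_L+1_1ss23TA	3798
50000	6	bmo-miR-71-3p_L-1R+1	13455
50000	6	gmo-miR-PC-5p-1276_891	1050
50000	7	gmo-miR-PC-3p-1433_822	863
50000	7	gmo-miR-PC-3p-803068_3	20
50000	7	bmo-miR-274-3p_L+1_1ss10GA	1215
50000	7	pxy-miR-274	6383
50000	7	pxy-mir-274-p3_1ss10TC	10
50000	7	gmo-miR-PC-5p-113242_14	19
50000	7	bmo-miR-252-5p	4031
50000	8	mse-miR-6094	19
50000	8	mse-mir-6094-p5_1ss7GA	19
50000	8	gmo-miR-PC-5p-201559_9	9
50000	9	dme-miR-8-3p_R+1	2914
50000	9	dme-miR-8-5p_R+1	13
50000	9	mse-mir-8-p5	3279
50000	10	dme-miR-276a-5p_L-1R-1_1ss22CT	1
50000	10	dme-miR-276b-3p_R+1_1ss10AC	47
50000	10	bmo-miR-276-5p	92
50000	11	bmo-miR-263a-5p_R+4	14803
50000	11	mse-miR-263a_R-1	21512
50000	12	bmo-miR-133	2828
50000	12	bmo-mir-133-p5	3
50000	12	tur-miR-1-3p_L-2R+1	10
50000	12	bmo-miR-1a-5p_R+1	38
50000	13	gmo-miR-PC-5p-237240_7	16
50000	13	gmo-miR-PC-5p-323567_7	20
50000	14	gmo-miR-PC-5p-1071846_2	5
50000	14	gmo-miR-PC-5p-1000352_3	4
50000	15	gmo-miR-PC-3p-812930_3	14.5
50000	15	gmo-miR-PC-5p-36514_40	121
50000	15	gmo-miR-PC-5p-130153_12	72.5
10000	1	bmo-miR-iab-4-3p_L-3R+1	10
10000	1	bmo-miR-iab-4-5p	59
10000	1	bmo-miR-iab-8_R+2	20
10000	2	bmo-miR-34-5p_R+1	1573
10000	2	bmo-miR-277-3p	8369
10000	2	bmo-miR-277-5p_L-1R+1	18.5
10000	3	gmo-miR-PC-3p-1153688_2	2
10000	3	mse-mir-278-p5	36
10000	4	gmo-miR-PC-3p-674_1493	17424
10000	4	gmo-miR-PC-5p-1018_1028	9152
10000	4	bmo-mir-6497-p3	2985
10000	4	bmo-mir-6497-p5	24686
10000	4	gmo-miR-PC-5p-1258_867	14307
10000	5	bmo-miR-10-3p	5036
10000	5	bmo-miR-10-5p_L+1	338584
10000	5	dme-miR-10-5p_L+1_1ss23TA	3798
10000	6	bmo-miR-71-3p_L-1R+1	13455
10000	6	gmo-miR-PC-5p-1276_891	1050
10000	7	gmo-miR-PC-3p-803068_3	20
10000	7	bmo-miR-274-3p_L+1_1ss10GA	1215
10000	7	pxy-miR-274	6383
10000	7	pxy-mir-274-p3_1ss10TC	10
10000	7	gmo-miR-PC-5p-113242_14	19
10000	7	bmo-miR-252-5p	4031
10000	8	mse-miR-6094	19
10000	8	mse-mir-6094-p5_1ss7GA	19
10000	8	gmo-miR-PC-5p-201559_9	9
10000	9	dme-miR-8-3p_R+1	2914
10000	9	dme-miR-8-5p_R+1	13
10000	9	mse-mir-8-p5	3279
10000	10	dme-miR-276a-5p_L-1R-1_1ss22CT	1
10000	10	dme-miR-276b-3p_R+1_1ss10AC	47
10000	10	bmo-miR-276-5p	92
10000	11	bmo-miR-263a-5p_R+4	14803
10000	11	mse-miR-263a_R-1	21512
10000	12	tur-miR-1-3p_L-2R+1	10
10000	12	bmo-miR-1a-5p_R+1	38
10000	13	gmo-miR-PC-5p-237240_7	16
10000	13	gmo-miR-PC-5p-323567_7	20
10000	14	gmo-miR-PC-5p-1071846_2	5
10000	14	gmo-miR-PC-5p-1000352_3	4
10000	15	gmo-miR-PC-3p-812930_3	14.5
10000	15	gmo-miR-PC-5p-36514_40	121
10000	15	gmo-miR-PC-5p-130153_12	72.5
5000	1	bmo-miR-iab-4-3p_L-3R+1	10
5000	1	bmo-miR-iab-4-5p	59
5000	1	bmo-miR-iab-8_R+2	20
5000	2	gmo-miR-PC-3p-1153688_2	2
5000	2	mse-mir-278-p5	36
5000	3	gmo-miR-PC-3p-674_1493	17424
5000	3	gmo-miR-PC-5p-1018_1028	9152
5000	3	bmo-mir-6497-p3	2985
5000	3	bmo-mir-6497-p5	24686
5000	4	bmo-miR-10-3p	5036
5000	4	bmo-miR-10-5p_L+1	338584
5000	4	dme-miR-10-5p_L+1_1ss23TA	3798
5000	5	bmo-miR-71-3p_L-1R+1	13455
5000	5	gmo-miR-PC-5p-1276_891	1050
5000	6	gmo-miR-PC-3p-803068_3	20
5000	6	bmo-miR-274-3p_L+1_1ss10GA	1215
5000	6	pxy-miR-274	6383
5000	6	pxy-mir-274-p3_1ss10TC	10
5000	7	mse-miR-6094	19
5000	7	mse-mir-6094-p5_1ss7GA	19
5000	7	gmo-miR-PC-5p-201559_9	9
5000	8	dme-miR-8-3p_R+1	2914
5000	8	dme-miR-8-5p_R+1	13
5000	8	mse-mir-8-p5	3279
5000	9	dme-miR-276a-5p_L-1R-1_1ss22CT	1
5000	9	dme-miR-276b-3p_R+1_1ss10AC	47
5000	9	bmo-miR-276-5p	92
5000	10	bmo-miR-263a-5p_R+4	14803
5000	10	mse-miR-263a_R-1	21512
5000	11	tur-miR-1-3p_L-2R+1	10
5000	11	bmo-miR-1a-5p_R+1	38
5000	12	gmo-miR-PC-5p-237240_7	16
5000	12	gmo-miR-PC-5p-323567_7	20
5000	13	gmo-miR-PC-5p-1071846_2	5
5000	13	gmo-miR-PC-5p-1000352_3	4
5000	14	gmo-miR-PC-3p-812930_3	14.5
5000	14	gmo-miR-PC-5p-36514_40	121
5000	14	gmo-miR-PC-5p-130153_12	72.5
3000	1	bmo-miR-iab-4-3p_L-3R+1	10
3000	1	bmo-miR-iab-4-5p	59
3000	1	bmo-miR-iab-8_R+2	20
3000	2	gmo-miR-PC-3p-1153688_2	2
3000	2	mse-mir-278-p5	36
3000	3	gmo-miR-PC-3p-674_1493	17424
3000	3	gmo-miR-PC-5p-1018_1028	9152
3000	3	bmo-mir-6497-p3	2985
3000	3	bmo-mir-6497-p5	24686
3000	4	bmo-miR-10-3p	5036
3000	4	bmo-miR-10-5p_L+1	338584
3000	4	dme-miR-10-5p_L+1_1ss23TA	3798
3000	5	gmo-miR-PC-3p-803068_3	20
3000	5	bmo-miR-274-3p_L+1_1ss10GA	1215
3000	5	pxy-miR-274	6383
3000	5	pxy-mir-274-p3_1ss10TC	10
3000	6	mse-miR-6094	19
3000	6	mse-mir-6094-p5_1ss7GA	19
3000	6	gmo-miR-PC-5p-201559_9	9
3000	7	dme-miR-8-3p_R+1	2914
3000	7	dme-miR-8-5p_R+1	13
3000	7	mse-mir-8-p5	3279
3000	8	dme-miR-276a-5p_L-1R-1_1ss22CT	1
3000	8	dme-miR-276b-3p_R+1_1ss10AC	47
3000	8	bmo-miR-276-5p	92
3000	9	bmo-miR-263a-5p_R+4	14803
3000	9	mse-miR-263a_R-1	21512
3000	10	tur-miR-1-3p_L-2R+1	10
3000	10	bmo-miR-1a-5p_R+1	38
3000	11	gmo-miR-PC-5p-237240_7	16
3000	11	gmo-miR-PC-5p-323567_7	20
3000	12	gmo-miR-PC-5p-1071846_2	5
3000	12	gmo-miR-PC-5p-1000352_3	4
3000	13	gmo-miR-PC-3p-812930_3	14.5
3000	13	gmo-miR-PC-5p-36514_40	121
3000	13	gmo-miR-PC-5p-130153_12	72.5
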
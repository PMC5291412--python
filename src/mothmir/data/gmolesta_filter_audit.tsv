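category	total_reads	unique_sequences
raw	16305575	2219608
adaptor_length	9804065	1660906
junk	24021	5511
rfam	477365	19662
rRNA	328485	12880
tRNA	62488	3557
snoRNA	804	227
snRNA	2343	555
other_rfam	83245	2443
repeats	5190	456
unique_reads	5998101	533252
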
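# Chromosome lengths and centromere intervals (1-based, bp).
# Centromere intervals are approximate, derived from standard cytoband/
# centromere annotations; adequate for arm assignment and telomere checks.
chrom	length	cen_start	cen_end
1	248956422	122026459	124932724
2	242193529	92188145	94090557
3	198295559	90772458	93655574
4	190214555	49712061	51743951
5	181538259	46485900	50059807
6	170805979	58553888	59829934
7	159345973	58169653	61528020
8	145138636	44033744	45877265
9	138394717	43389635	45518558
10	133797422	39686682	41593521
11	135086622	51078348	54425074
12	133275309	34769407	37185252
13	114364328	16000000	18051248
14	107043718	16000000	18173523
15	101991189	17083673	19725254
16	90338345	36311158	38265669
17	83257441	22813679	26616164
18	80373285	15460899	20861206
19	58617616	24498980	27190874
20	64444167	26436232	30038348
21	46709983	10864560	12915808
22	50818468	12954788	15054318
X	156040895	58605579	62412542
Y	57227415	10316944	10544039
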
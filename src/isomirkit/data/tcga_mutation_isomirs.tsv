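contrast	label	sequence	type	p_adj	regulation	effect	effect_scale
NF1_mut_vs_wt	hsa-miR-766-3p|0|-2	ACTCCAGCCCCACAGCCTCA	end-site	7.77E-02	up	1.17	log2
NF1_mut_vs_wt	hsa-miR-584-5p|-1|-2	ATTATGGTTTGCCTGGGACTG	mixed: start-site + end-site	8.38E-02	up	1.46	log2
NF1_mut_vs_wt	hsa-miR-378a-3p|-1|-1(+1U)	CACTGGACTTGGAGTCAGAAGGT	mixed: shifted + 3' non-templated addition	7.77E-02	down	-1.35	log2
NF1_mut_vs_wt	hsa-let-7d-5p|+1|-1	GAGGTAGTAGGTTGCATAGT	mixed: start-site + end-site	9.29E-02	up	0.70	log2
NF1_mut_vs_wt	hsa-miR-148a-3p|+3|-1	GTGCACTACAGAACTTTG	mixed: start-site + end-site	7.77E-02	up	1.03	log2
BRAF_mut_vs_wt	hsa-let-7d-3p|0|-2(+2U)	CTATACGACCTGCTGCCTTTTT	mixed: end-site + 3' non-templated addition	4.40E-02	up	0.76	log2
BRAF_mut_vs_wt	hsa-let-7i-3p|0|-2	CTGCGCAAGCTACTGCCTTG	end-site	2.12E-02	up	1.75	log2
BRAF_mut_vs_wt	hsa-miR-100-5p|+1|-1	ACCCGTAGATCCGAACTTGT	mixed: start-site + end-site	2.14E-02	up	1.96	log2
BRAF_mut_vs_wt	hsa-miR-100-5p|0|-1	AACCCGTAGATCCGAACTTGT	end-site	2.02E-02	up	2.00	log2
BRAF_mut_vs_wt	hsa-miR-100-5p|0|-1(+2U)	AACCCGTAGATCCGAACTTGTTT	mixed: end-site + 3' non-templated addition	7.63E-07	up	1.39	log2
BRAF_mut_vs_wt	hsa-miR-106b-3p|+1|-1	CGCACTGTGGGTACTTGCTG	mixed: start-site + end-site	4.49E-03	up	0.81	log2
BRAF_mut_vs_wt	hsa-miR-1247-5p|0|-1	ACCCGTCCCGTTCGTCCCCGG	end-site	2.02E-02	up	0.96	log2
BRAF_mut_vs_wt	hsa-miR-125b-5p|0|+1	TCCCTGAGACCCTAACTTGTGAG	end-site	2.44E-04	up	0.86	log2
BRAF_mut_vs_wt	hsa-miR-1307-3p|0|-2	ACTCGGCGTGGCGTCGGTCG	end-site	3.05E-02	up	0.80	log2
BRAF_mut_vs_wt	hsa-miR-143-3p|0|-3(+1U)	TGAGATGAAGCACTGTAGT	mixed: end-site + 3' non-templated addition	3.95E-02	up	1.06	log2
BRAF_mut_vs_wt	hsa-miR-143-3p|-1|-1	CTGAGATGAAGCACTGTAGCT	shifted	4.64E-02	up	1.03	log2
BRAF_mut_vs_wt	hsa-miR-143-3p|-1|-3	CTGAGATGAAGCACTGTAG	mixed: start-site + end-site	2.59E-02	up	1.21	log2
BRAF_mut_vs_wt	hsa-miR-146a-5p|0|-4	TGAGAACTGAATTCCATG	end-site	3.11E-02	up	0.87	log2
BRAF_mut_vs_wt	hsa-miR-154-5p|0|0	TAGGTTATCCGTGTTGCCTTCG	canonical	8.45E-03	up	0.94	log2
BRAF_mut_vs_wt	hsa-miR-181a-2-3p|0|+1	ACCACTGACCGTTGACTGTACCT	end-site	2.17E-02	down	-1.57	log2
BRAF_mut_vs_wt	hsa-miR-181c-5p|0|0	AACATTCAACCTGTCGGTGAGT	canonical	8.45E-03	up	1.07	log2
BRAF_mut_vs_wt	hsa-miR-199a-3p|+3|-1	GTAGTCTGCACATTGGTT	mixed: start-site + end-site	4.49E-03	up	0.82	log2
BRAF_mut_vs_wt	hsa-miR-204-5p|0|0	TTCCCTTTGTCATCCTATGCCT	canonical	1.91E-02	up	1.95	log2
BRAF_mut_vs_wt	hsa-miR-204-5p|0|0(+2U)	TTCCCTTTGTCATCCTATGCCTTT	3' non-templated addition	2.46E-02	up	0.87	log2
BRAF_mut_vs_wt	hsa-miR-204-5p|0|-1	TTCCCTTTGTCATCCTATGCC	end-site	1.40E-02	up	2.09	log2
BRAF_mut_vs_wt	hsa-miR-204-5p|0|-2	TTCCCTTTGTCATCCTATGC	end-site	1.60E-02	up	1.76	log2
BRAF_mut_vs_wt	hsa-miR-214-5p|+1|0	GCCTGTCTACACTTGCTGTGC	start-site	2.59E-02	up	0.96	log2
BRAF_mut_vs_wt	hsa-miR-296-3p|0|-2	GAGGGTTGGGTGGAGGCTCT	end-site	3.53E-05	up	0.98	log2
BRAF_mut_vs_wt	hsa-miR-29a-3p|0|-4(+2U)	TAGCACCATCTGAAATCGTT	mixed: end-site + 3' non-templated addition	4.15E-03	up	0.85	log2
BRAF_mut_vs_wt	hsa-miR-30c-2-3p|0|-2	CTGGGAGAAGGCTGTTTACT	end-site	1.39E-02	up	0.72	log2
BRAF_mut_vs_wt	hsa-miR-330-5p|0|-1	TCTCTGGGCCTGTGTCTTAGG	end-site	2.54E-02	up	0.78	log2
BRAF_mut_vs_wt	hsa-miR-342-3p|0|0(+1U)	TCTCACACAGAAATCGCACCCGTT	3' non-templated addition	4.49E-03	up	0.70	log2
BRAF_mut_vs_wt	hsa-miR-342-5p|+1|+2	GGGGTGCTATCTGTGATTGAGG	mixed: start-site + end-site	1.09E-02	up	0.61	log2
BRAF_mut_vs_wt	hsa-miR-381-3p|0|0	TATACAAGGGCAAGCTCTCTGT	canonical	2.52E-02	up	0.94	log2
BRAF_mut_vs_wt	hsa-miR-409-5p|0|0	AGGTTACCCGAGCAACTTTGCAT	canonical	4.97E-02	up	0.93	log2
BRAF_mut_vs_wt	hsa-miR-423-5p|0|-2	TGAGGGGCAGAGAGCGAGACT	end-site	2.54E-02	up	1.06	log2
BRAF_mut_vs_wt	hsa-miR-432-5p|0|-1(+1U)	TCTTGGAGTAGGTCATTGGGTGT	mixed: end-site + 3' non-templated addition	4.64E-02	up	1.00	log2
BRAF_mut_vs_wt	hsa-miR-485-3p|0|0	GTCATACACGGCTCTCCTCTCT	canonical	3.05E-02	up	0.90	log2
BRAF_mut_vs_wt	hsa-miR-493-3p|0|-1	TGAAGGTCTACTGTGTGCCAG	end-site	9.25E-03	up	0.92	log2
BRAF_mut_vs_wt	hsa-miR-495-3p|0|0	AAACAAACATGGTGCACTTCTT	canonical	8.45E-03	up	0.89	log2
BRAF_mut_vs_wt	hsa-miR-518a-3p|0|0	GAAAGCGCTTCCCTTTGCTGGA	canonical	1.91E-02	up	2.55	log2
BRAF_mut_vs_wt	hsa-miR-519a-5p|-1|-1	ACTCTAGAGGGAAGCGCTTTCT	shifted	2.44E-04	up	3.59	log2
BRAF_mut_vs_wt	hsa-miR-625-3p|+1|-1(+1U)	ACTATAGAACTTTCCCCCTCT	mixed: start-site + end-site + 3' non-templated addition	3.90E-02	up	0.85	log2
BRAF_mut_vs_wt	hsa-miR-671-3p|0|0	TCCGGTTCTCAGGGCTCCACC	canonical	3.95E-02	up	0.84	log2
BRAF_mut_vs_wt	hsa-miR-6892-5p|0|-1	GTAAGGGACCGGAGAGTAGG	end-site	2.44E-04	up	0.89	log2
BRAF_mut_vs_wt	hsa-miR-758-5p|+2|+1	TGGTTGACCAGAGAGCACACG	mixed: start-site + end-site	1.90E-03	up	0.91	log2
BRAF_mut_vs_wt	hsa-miR-92a-3p|0|+1(+1U)	TATTGCACTTGTCCCGGCCTGTGT	mixed: end-site + 3' non-templated addition	2.14E-02	down	-1.31	log2
BRAF_mut_vs_wt	hsa-miR-937-3p|0|-2	ATCCGCGCTCTGACTCTCTG	end-site	6.44E-03	up	1.09	log2
BRAF_mut_vs_wt	hsa-miR-942-5p|0|-2	TCTTCTCTGTTTTGGCCATG	end-site	7.63E-07	up	0.93	log2
BRAF_V600E_vs_wt	hsa-let-7b-5p|0|-1	TGAGGTAGTAGGTTGTGTGGT	end-site	2.89E-02	up	2.13	linear
BRAF_V600E_vs_wt	hsa-let-7b-5p|0|-2	TGAGGTAGTAGGTTGTGTGG	end-site	2.62E-02	up	2.32	linear
BRAF_V600E_vs_wt	hsa-miR-100-5p|+1|-1	ACCCGTAGATCCGAACTTGT	mixed: start-site + end-site	2.34E-02	up	4.35	linear
BRAF_V600E_vs_wt	hsa-miR-100-5p|0|0	AACCCGTAGATCCGAACTTGTG	canonical	2.62E-02	up	3.62	linear
BRAF_V600E_vs_wt	hsa-miR-100-5p|0|-1	AACCCGTAGATCCGAACTTGT	end-site	8.90E-03	up	4.59	linear
BRAF_V600E_vs_wt	hsa-miR-125b-5p|0|0	TCCCTGAGACCCTAACTTGTGA	canonical	3.23E-02	up	2.70	linear
BRAF_V600E_vs_wt	hsa-miR-125b-5p|0|-1	TCCCTGAGACCCTAACTTGTG	end-site	2.62E-02	up	3.02	linear
BRAF_V600E_vs_wt	hsa-miR-146b-3p|0|0	GCCCTGTGGACTCAGTTCTGGT	canonical	1.46E-02	up	2.33	linear
BRAF_V600E_vs_wt	hsa-miR-181c-5p|0|0	AACATTCAACCTGTCGGTGAGT	canonical	2.62E-02	up	2.22	linear
BRAF_V600E_vs_wt	hsa-miR-204-5p|0|0	TTCCCTTTGTCATCCTATGCCT	canonical	2.89E-02	up	4.63	linear
BRAF_V600E_vs_wt	hsa-miR-181a-2-3p|0|+1	ACCACTGACCGTTGACTGTACCT	end-site	2.41E-02	down	-2.91	linear
BRAF_V600E_vs_wt	hsa-miR-181a-2-3p|-1|-1	AACCACTGACCGTTGACTGTAC	shifted	4.83E-02	down	-2.29	linear
BRAF_V600EM_vs_V600E	hsa-let-7b-3p|0|-1(+1U)	CTATACAACCTACTGCCTTCCT	mixed: end-site + 3' non-templated addition	3.969E-02	down	-2.30	linear
BRAF_V600EM_vs_V600E	hsa-miR-100-5p|0|0(+1U)	AACCCGTAGATCCGAACTTGTGT	3' non-templated addition	3.969E-02	down	-4.14	linear
BRAF_V600EM_vs_V600E	hsa-miR-125b-5p|0|0	TCCCTGAGACCCTAACTTGTGA	canonical	3.969E-02	down	-2.77	linear
BRAF_V600EM_vs_V600E	hsa-miR-221-3p|0|-1	AGCTACATTGTCTGCTGGGTTT	end-site	3.969E-02	down	-2.29	linear
BRAF_V600EM_vs_V600E	hsa-let-7a-5p|+1|-2	GAGGTAGTAGGTTGTATAG	mixed: start-site + end-site	3.969E-02	up	2.14	linear
BRAF_V600EM_vs_V600E	hsa-miR-1247-5p|0|-1	ACCCGTCCCGTTCGTCCCCGG	end-site	3.969E-02	up	4.07	linear
BRAF_V600EM_vs_V600E	hsa-miR-219a-1-3p|0|0	AGAGTTGAGTCTGGACGTCCCG	canonical	3.969E-02	up	1.75	linear
NRAS_mut_vs_wt	hsa-miR-17-3p|+1|0	CTGCAGTGAAGGCACTTGTAG	start-site	8.11E-02	up	0.92	log2
NRAS_mut_vs_wt	hsa-miR-17-3p|0|0	ACTGCAGTGAAGGCACTTGTAG	canonical	2.11E-02	up	0.85	log2
NRAS_mut_vs_wt	hsa-miR-19b-3p|0|-1	TGTGCAAATCCATGCAAAACTG	end-site	8.11E-02	up	0.79	log2
NRAS_mut_vs_wt	hsa-miR-20a-5p|0|-2	TAAAGTGCTTATAGTGCAGGT	end-site	7.26E-02	up	0.85	log2
NRAS_mut_vs_wt	hsa-miR-3614-5p|0|-1	CCACTTGGATCTGAAGGCTGCC	end-site	8.11E-02	up	0.85	log2
NRAS_mut_vs_wt	hsa-miR-509-3p|+4|+1	TGGTACGTCTGTGGGTAGA	mixed: start-site + end-site	4.66E-02	down	-1.10	log2
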
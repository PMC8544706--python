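label	isomir_mean	canonical_mean	ratio
hsa-miR-222-3p|0|+3	170.56	3.17	53.84
hsa-miR-141-3p|0|-1	127.96	4.26	30.01
hsa-miR-30a-5p|0|+2	234.85	10.41	22.55
hsa-miR-222-3p|0|+4	48.31	3.17	15.25
hsa-miR-222-3p|0|+2	38.26	3.17	12.08
hsa-miR-30d-5p|0|+2	462.00	39.70	11.64
hsa-miR-200b-3p|0|+1	44.59	4.29	10.39
hsa-miR-125a-5p|0|-2	623.96	60.29	10.35
hsa-miR-30c-5p|0|+1	153.33	15.63	9.81
hsa-miR-200b-3p|0|+1(+1U)	33.28	4.29	7.76
hsa-miR-10b-5p|0|-1	2368.09	365.48	6.48
hsa-miR-30a-5p|0|-2	57.72	10.41	5.54
hsa-miR-19b-3p|0|-1	25.74	4.85	5.31
hsa-miR-199a-3p|0|-1	258.78	52.96	4.89
hsa-miR-26b-5p|0|+1	165.47	35.93	4.61
hsa-miR-30a-5p|0|+1	46.17	10.41	4.43
hsa-miR-27a-3p|0|-1	100.82	24.74	4.08
hsa-miR-30d-5p|0|+1	135.04	39.70	3.40
hsa-miR-221-3p|0|-1	39.05	11.80	3.31
hsa-miR-10a-5p|0|-1	594.23	197.37	3.01
hsa-miR-744-5p|0|-1	24.67	9.36	2.63
hsa-miR-30a-5p|0|-1	23.98	10.41	2.30
hsa-miR-27b-3p|0|-1	845.19	368.31	2.29
hsa-miR-101-3p|0|0(+1U)	47.54	21.42	2.22
hsa-miR-221-3p|0|-2	26.12	11.80	2.21
hsa-miR-509-3p|0|+1	88.74	40.27	2.20
hsa-miR-203a-3p|+1|0(+1U)	268.82	134.91	1.99
hsa-miR-101-3p|0|+1	39.31	21.42	1.83
hsa-miR-199a-3p|-1|-1	87.92	52.96	1.66
hsa-miR-29a-3p|0|-1	33.98	21.58	1.57
hsa-miR-30d-5p|0|-2	61.55	39.70	1.55
hsa-miR-203a-3p|0|+1	189.30	134.91	1.40
hsa-miR-142-5p|-2|-3	97.82	76.36	1.28
hsa-miR-125a-5p|0|-3	73.56	60.29	1.22
hsa-miR-205-5p|0|+1	1221.77	1044.60	1.17
hsa-miR-30d-5p|0|-1	45.81	39.70	1.15
hsa-miR-101-3p|-1|-1	23.09	21.42	1.08
hsa-miR-146b-5p|0|+1	35.42	33.14	1.07
hsa-miR-27a-3p|0|-2	25.16	24.74	1.02
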
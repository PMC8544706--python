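label	p_adj	regulation	log_fc
hsa-let-7b-5p|0|0	1.0E-02	up	2.73
hsa-miR-205-5p|0|0	9.3E-03	up	2.04
hsa-miR-143-3p|0|0	4.2E-02	up	1.50
hsa-miR-27a-3p|0|0	7.1E-03	down	-1.60
hsa-miR-192-5p|0|0	3.9E-02	down	-1.61
hsa-miR-99a-5p|0|0	2.1E-02	down	-1.77
hsa-miR-99b-5p|0|0	3.6E-02	down	-1.94
hsa-miR-28-3p|0|0	1.1E-02	down	-1.99
hsa-miR-181a-2-3p|0|0	5.8E-04	down	-2.05
hsa-miR-497-5p|0|0	3.4E-04	down	-2.27
hsa-miR-148a-3p|0|0	2.7E-03	down	-2.29
hsa-miR-30b-5p|0|0	3.3E-03	down	-2.47
hsa-miR-199a-3p|0|0	1.5E-05	down	-3.07
hsa-miR-101-3p|0|0	4.2E-05	down	-3.08
hsa-miR-199a-5p|0|0	8.9E-07	down	-3.21
hsa-miR-27b-3p|0|0	3.2E-06	down	-3.38
hsa-miR-125b-5p|0|0	9.6E-07	down	-3.98
hsa-miR-29a-3p|0|0	8.6E-09	down	-6.42
hsa-let-7b-5p|0|+1	5.6E-03	up	2.54
hsa-miR-30d-5p|0|+2	7.2E-03	up	2.25
hsa-miR-30a-5p|0|+2	1.3E-03	up	2.17
hsa-miR-222-3p|0|+3	9.0E-03	up	2.00
hsa-miR-143-3p|0|0(+1U)	2.6E-02	up	1.71
hsa-miR-143-3p|0|-1	4.5E-02	up	1.70
hsa-miR-203a-3p|+1|0(+1U)	4.2E-02	up	1.46
hsa-miR-199a-3p|+1|-1	2.0E-02	down	-1.19
hsa-miR-30a-5p|0|-1	1.7E-02	down	-1.28
hsa-miR-30a-5p|0|-2	4.5E-02	down	-1.36
hsa-miR-26a-5p|+3|0	4.3E-02	down	-1.44
hsa-miR-103a-3p|0|-1(+1U)	3.2E-02	down	-1.57
hsa-miR-27b-3p|0|0(+1U)	5.0E-02	down	-1.57
hsa-miR-26a-5p|0|-1	2.0E-02	down	-1.64
hsa-miR-148a-3p|0|+1	3.2E-02	down	-1.73
hsa-miR-148a-3p|0|+2	1.7E-02	down	-1.75
hsa-miR-27b-3p|0|-1	2.7E-02	down	-1.78
hsa-miR-23b-3p|+3|-2	6.8E-03	down	-1.87
hsa-miR-148a-3p|0|0(+1U)	1.2E-02	down	-1.90
hsa-miR-26a-5p|0|0(+2U)	1.6E-04	down	-2.06
hsa-miR-27a-3p|0|-2	3.1E-03	down	-2.10
hsa-miR-101-3p|0|0(+1U)	2.7E-03	down	-2.12
hsa-miR-30e-5p|0|+1	4.8E-04	down	-2.35
hsa-miR-141-3p|0|-1	3.8E-03	down	-2.36
hsa-miR-30d-5p|0|-1	8.5E-03	down	-2.46
hsa-miR-99b-5p|0|-1	1.1E-02	down	-2.53
hsa-miR-199a-5p|0|-1	6.1E-06	down	-2.79
hsa-miR-27a-3p|0|-1	1.3E-03	down	-2.81
hsa-miR-19b-3p|0|-1	2.6E-04	down	-3.02
hsa-miR-101-3p|0|+1	3.4E-05	down	-3.15
hsa-miR-27b-3p|0|-2	3.4E-05	down	-3.23
hsa-miR-100-5p|0|-1	1.3E-03	down	-3.50
hsa-miR-27b-3p|0|+1	4.7E-06	down	-3.51
hsa-miR-27a-3p|0|-3	9.6E-07	down	-3.89
hsa-miR-27b-3p|0|-1(+1U)	1.2E-06	down	-3.95
hsa-miR-101-3p|-1|-1	1.2E-06	down	-4.70
hsa-miR-29a-3p|0|-1	4.0E-08	down	-5.79
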
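label	trend
hsa-miR-19b-3p|0|0	down
hsa-miR-19b-3p|0|-1	down
hsa-miR-27a-3p|0|0	down
hsa-miR-27a-3p|0|-1	down
hsa-miR-27a-3p|0|-2	down
hsa-miR-27a-3p|0|-3	down
hsa-miR-29a-3p|0|0	down
hsa-miR-29a-3p|0|-1	down
hsa-miR-222-3p|0|0	up
hsa-miR-222-3p|0|+3	up
hsa-miR-101-3p|0|0	down
hsa-miR-101-3p|0|0(+1U)	down
hsa-miR-101-3p|0|+1	down
hsa-miR-101-3p|-1|-1	down
hsa-miR-27b-3p|0|0	down
hsa-miR-27b-3p|0|0(+1U)	down
hsa-miR-27b-3p|0|-1	down
hsa-miR-27b-3p|0|-2	down
hsa-miR-27b-3p|0|+1	down
hsa-miR-27b-3p|0|-1(+1U)	down
hsa-miR-141-3p|0|-1	down
hsa-miR-141-3p|0|0	flat
hsa-miR-141-3p|0|+1	flat
hsa-miR-30a-5p|0|+2	up
hsa-miR-30a-5p|0|-1	down
hsa-miR-30a-5p|0|-2	down
hsa-miR-30a-5p|0|0(+1U)	down
hsa-miR-30d-5p|0|-1	down
hsa-miR-30d-5p|0|+2	up
hsa-miR-30d-5p|0|0	flat
hsa-miR-203a-3p|0|-1	down
hsa-miR-203a-3p|0|+1	down
hsa-miR-203a-3p|+1|0(+1U)	up
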
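mirna	top_form_cm	top_form_bn
hsa-miR-19b-3p	hsa-miR-19b-3p|0|-1	hsa-miR-19b-3p|0|-1
hsa-miR-27a-3p	hsa-miR-27a-3p|0|-1	hsa-miR-27a-3p|0|-1
hsa-miR-29a-3p	hsa-miR-29a-3p|0|-1	hsa-miR-29a-3p|0|-1
hsa-miR-222-3p	hsa-miR-222-3p|0|+3	hsa-miR-222-3p|0|+3
hsa-miR-101-3p	hsa-miR-101-3p|0|0(+1U)	hsa-miR-101-3p|-1|-1
hsa-miR-27b-3p	hsa-miR-27b-3p|0|-1	hsa-miR-27b-3p|0|0
hsa-miR-141-3p	hsa-miR-141-3p|0|-1	hsa-miR-141-3p|0|-1
hsa-miR-30a-5p	hsa-miR-30a-5p|0|+2	hsa-miR-30a-5p|0|-2
hsa-miR-30d-5p	hsa-miR-30d-5p|0|-1	hsa-miR-30d-5p|0|+2
hsa-miR-203a-3p	hsa-miR-203a-3p|+1|0(+1U)	hsa-miR-203a-3p|0|+1
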
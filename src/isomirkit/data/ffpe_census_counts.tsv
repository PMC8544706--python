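key	count
canonical_with_isomir	90
canonical_without_isomir	40
isomir_with_canonical	324
orphan_isomir	40
end-site	199
start-site	19
shifted	9
3p-nta	43
mixed:start-site+end-site	13
mixed:end-site+3p-nta	34
mixed:start-site+3p-nta	6
mixed:shifted+3p-nta	1
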
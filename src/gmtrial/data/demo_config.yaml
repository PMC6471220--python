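# Demo pipeline configuration: simulate a range-finding dose trial, a
# natural-response-variation reference trial and a GM/WT/NS case study with
# a transformation-process shift, then derive endpoints, run the group
# statistics and test distribution-wise equivalence.
seed: 42
stages: [simulate, endpoints, stats, equivalence]
control_diet: sub0
substitution:
  design: range_finding
reference: {}
case_study:
  arm_shifts:
    length_adult: {GM: 1.5, NS: 1.5}
    liver_protein_content: {GM: 1.5, NS: 1.5}
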
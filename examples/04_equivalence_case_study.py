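"""Distribution-wise equivalence of a GM maize against its WT and NS controls.

Simulates the three-arm case study with a transformation-process effect: a
1.5-EL shift shared by the GM and null-segregant (NS) arms but absent from
the wild type (WT), then classifies every endpoint x contrast against
equivalence limits derived from the reference-variety trial.
"""

from gmtrial import (
    SimulationConfig,
    equivalence_report,
    generate_equivalence_case_study,
    generate_reference_dataset,
)

ref = generate_reference_dataset(SimulationConfig(design="natural_variation"),
                                 seed=42)
case = generate_equivalence_case_study(
    SimulationConfig(
        design="equivalence_case_study",
        arm_shifts={"length_adult": {"GM": 1.5, "NS": 1.5},
                    "liver_protein_content": {"GM": 1.5, "NS": 1.5}},
    ),
    seed=43,
)

report = equivalence_report(case, ref)
ok = report[report["error"] == ""]
cols = ["endpoint_name", "sex_stratum", "contrast", "scaled_estimate",
        "ci_low", "ci_high", "verdict"]
print(ok[cols].round(3).to_string(index=False))

print("\nEstimates are EL-scaled mean differences; the equivalence region is")
print("(-1, +1). For the shifted endpoints the GM-vs-NS contrast stays near")
print("zero (both arms carry the transformation-process effect) while both")
print("contrasts against WT sit near +1.5 EL — the signature that the")
print("transformation process, not the transgene, moved the response. Note")
print("how often CIs at 3 tanks/group spill past the limits even for truly")
print("equivalent arms: proof of equivalence demands more replication.")
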
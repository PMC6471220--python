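"""Simulate the maize-substitution range-finding trial and test dose effects.

Generates a trial with the study design (6 substitution levels + commercial
control, 3 tanks of 20 fish), derives the endpoint table, and runs the
conventional statistics: tank-level ANOVA, Dunnett comparisons against the
0 % diet, and the Pearson dose correlation for the absolute growth rate.
"""

import numpy as np

from gmtrial import (
    SimulationConfig,
    anova_replicate_level,
    build_endpoint_table,
    ccd_comparison,
    dose_correlation,
    dunnett_vs_control,
    fit_length_weight,
    generate_substitution_trial,
)

cfg = SimulationConfig(design="range_finding")
trial = generate_substitution_trial(cfg, seed=42)
model = fit_length_weight(trial.fish, day=0)
print(f"length-weight fit at day 0: W = {model.a:.3g} * L^{model.b:.3f} "
      f"(n = {model.n_fish})")

table = build_endpoint_table(trial, model)
agr = {d: v for d, v in table.values_by_diet("AGR").items() if d != "CCD"}
sub = dict(zip(trial.diets["diet_id"], trial.diets["substitution_pct"]))

an = anova_replicate_level(agr, "AGR")
print(f"\nAGR tank-level ANOVA: F({an.df_num},{an.df_den}) = {an.F:.2f}, "
      f"p = {an.p_value:.4f}")

dn = dunnett_vs_control(agr, "sub0", "AGR")
print("Dunnett vs 0 % maize (two-sided adjusted p):")
for comp in sorted(dn.comparisons, key=lambda c: sub[c.diet_id]):
    print(f"  {comp.diet_id:>6}: diff = {comp.mean_diff:+.4f} mm/day, "
          f"p_adj = {comp.p_adjusted:.4f}")

x = np.concatenate([[sub[d]] * len(v) for d, v in agr.items()])
y = np.concatenate(list(agr.values()))
corr = dose_correlation(x, y)
print(f"Pearson dose correlation: r = {corr.r:.3f}, p = {corr.p:.2e}")

ccd = ccd_comparison(table.values_by_diet("AGR")["sub0"],
                     table.values_by_diet("AGR")["CCD"])
print(f"0 % maize vs commercial control: t = {ccd.t:.2f}, p = {ccd.p:.3f}")
print("\nGrowth declines with the maize substitution level (negative dose")
print("correlation; the highest levels separate from 0 % under Dunnett),")
print("while the 0 % experimental diet is indistinguishable from the")
print("commercial feed — the formulation itself is adequate.")
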
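"""Synthetic feeding-trial generator with the study's hierarchical structure.

Emulates three designs: the maize-substitution dose series (6 levels plus a
commercial control diet, 3 tanks of 20 fish each), the natural-response-
variation trial (10 reference maize varieties at a fixed 15 % substitution),
and the three-arm GM / wild-type / null-segregant case study.  Every random
quantity is drawn from a hierarchically split stream (trial → tank → fish),
so a (config, seed) pair fully determines the dataset and the configured
effect sizes and variance components serve as oracles for the analysis
pipeline.

Endpoint noise families: normal for lengths and rates of change, lognormal
(additive effects on the log scale) for strictly positive endpoints such as
somatic indices and energy reserves, binomial for offspring survival and
hatching counts.  Between-replicate (tank) SDs default to 0.4 × the
between-variety SD, which makes 3-tank confidence intervals broad relative
to the equivalence-limit range — the replication realism the analysis is
meant to confront.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit

from .core_model import TrialDataset, ENDPOINT_COLUMNS
from .endpoints import EndpointTable, load_range_finding_diets

__all__ = [
    "EndpointSpec",
    "SimulationConfig",
    "DEFAULT_ENDPOINT_SPECS",
    "generate_substitution_trial",
    "generate_reference_dataset",
    "generate_equivalence_case_study",
]


class EndpointSpec(BaseModel):
    """Noise model of one endpoint in the reference/case-study trials.

    ``sigma_*`` are SDs of the zero-mean variety / trial / tank / fish
    effects on the endpoint's link scale (identity for normal, log for
    lognormal, logit for binomial).  ``baseline`` may be a per-sex mapping
    for sex-specific endpoints.
    """

    name: str
    family: Literal["normal", "lognormal", "binomial"] = "normal"
    level: Literal["fish", "tank"] = "tank"
    baseline: float | dict[str, float]
    sigma_variety: float = Field(ge=0)
    sigma_trial: float = Field(0.0, ge=0)
    sigma_tank: float = Field(ge=0)
    sigma_fish: float = Field(0.0, ge=0)
    sex_specific: bool = False
    n_binomial: int = 48

    def strata(self) -> tuple[str, ...]:
        return ("male", "female") if self.sex_specific else ("pooled",)

    def base(self, stratum: str) -> float:
        if isinstance(self.baseline, dict):
            return self.baseline[stratum]
        return self.baseline

    def link(self, stratum: str) -> float:
        b = self.base(stratum)
        if self.family == "lognormal":
            return float(np.log(b))
        if self.family == "binomial":
            return float(logit(b))
        return float(b)

    def from_link(self, eta, rng: np.random.Generator | None = None):
        eta = np.asarray(eta, dtype=float)
        if self.family == "lognormal":
            return np.exp(eta)
        if self.family == "binomial":
            p = expit(eta)
            if rng is None:
                return p
            return rng.binomial(self.n_binomial, p) / self.n_binomial
        return eta


def _default_endpoint_specs() -> list[EndpointSpec]:
    mk = EndpointSpec
    return [
        mk(name="length_adult", family="normal", level="fish", baseline=36.0,
           sigma_variety=1.0, sigma_tank=0.4, sigma_fish=2.0),
        mk(name="RCF", family="normal", level="fish", baseline=1.0,
           sigma_variety=0.03, sigma_tank=0.012, sigma_fish=0.13),
        mk(name="HSI", family="lognormal", level="tank",
           baseline={"male": 1.2, "female": 2.2}, sex_specific=True,
           sigma_variety=0.08, sigma_tank=0.032),
        mk(name="GSI", family="lognormal", level="tank",
           baseline={"male": 1.3, "female": 8.0}, sex_specific=True,
           sigma_variety=0.12, sigma_tank=0.048),
        mk(name="liver_carbohydrate_content", family="lognormal", level="tank",
           baseline={"male": 4.0, "female": 5.0}, sex_specific=True,
           sigma_variety=0.35, sigma_tank=0.14),
        mk(name="liver_protein_content", family="lognormal", level="tank",
           baseline={"male": 12.0, "female": 14.0}, sex_specific=True,
           sigma_variety=0.18, sigma_tank=0.072),
        mk(name="liver_lipid_content", family="lognormal", level="tank",
           baseline={"male": 6.0, "female": 7.0}, sex_specific=True,
           sigma_variety=0.30, sigma_tank=0.12),
        mk(name="muscle_protein_conc", family="lognormal", level="tank",
           baseline={"male": 180.0, "female": 175.0}, sex_specific=True,
           sigma_variety=0.10, sigma_tank=0.04),
        mk(name="fertility_rate", family="binomial", level="tank", baseline=0.80,
           sigma_variety=0.30, sigma_tank=0.12, n_binomial=100),
        mk(name="hatching_rate_96hpf", family="binomial", level="tank",
           baseline=0.95, sigma_variety=0.30, sigma_tank=0.12, n_binomial=48),
        mk(name="mortality_96hpf", family="binomial", level="tank", baseline=0.08,
           sigma_variety=0.30, sigma_tank=0.12, n_binomial=48),
        mk(name="length_larval", family="normal", level="tank", baseline=3.9,
           sigma_variety=0.08, sigma_tank=0.032),
        mk(name="swimming_distance", family="normal", level="tank",
           baseline=1800.0, sigma_variety=120.0, sigma_tank=48.0),
    ]


DEFAULT_ENDPOINT_SPECS = _default_endpoint_specs()


class SimulationConfig(BaseModel):
    """Full description of a simulated feeding trial.

    Defaults follow the study conditions: 3 replicate tanks per diet group,
    20 fish per tank (10 per sex), substitution levels 0–25 % in 5 % steps,
    a daily ration of 2.5 % of the tanks' mean initial wet weight, 28-day
    dose trials and 84-day reference/case-study trials.
    """

    design: Literal[
        "range_finding",
        "artemia_supplementation",
        "natural_variation",
        "equivalence_case_study",
    ]
    n_varieties: int = Field(10, ge=1)
    n_trials: int = Field(1, ge=1)
    n_tanks_per_diet: int = Field(3, ge=1)
    n_fish_per_tank: int = Field(20, ge=2)
    substitution_levels: list[float] = Field(
        default_factory=lambda: [0.0, 5.0, 10.0, 15.0, 20.0, 25.0]
    )
    include_ccd: bool = True
    duration_days: int = Field(28, gt=0)
    ration_fraction: float = Field(0.025, gt=0)

    # day-0 fish morphometry
    allometry_a: float = Field(1.05e-5, gt=0)
    allometry_b: float = 3.0
    length_mean_mm: float = 34.0
    length_sd_mm: float = Field(2.5, ge=0)
    weight_log_sd: float = Field(0.13, ge=0)

    # dose-trial effect injections (per % maize substitution)
    agr_baseline_mm_day: float = 0.11
    agr_dose_slope: float = -0.002
    agr_sigma_tank: float = Field(0.012, ge=0)
    growth_sigma_fish_mm: float = Field(0.8, ge=0)
    hsi_dose_slope_male: float = 0.012
    hsi_sigma_tank: float = Field(0.08, ge=0)
    uptake_baseline_pct: dict[str, float] = Field(
        default_factory=lambda: {"carbohydrate": 85.0, "protein": 90.0,
                                 "lipid": 92.0}
    )
    carb_uptake_dose_slope: float = -0.35
    uptake_sigma_tank: float = Field(2.0, ge=0)

    # case-study arm shifts, in EL units (multiples of sigma_variety on the
    # endpoint's link scale); e.g. {"length_adult": {"GM": 1.5, "NS": 1.5}}
    arm_shifts: dict[str, dict[str, float]] = Field(default_factory=dict)

    endpoints: list[EndpointSpec] = Field(default_factory=_default_endpoint_specs)

    @model_validator(mode="after")
    def _check(self):
        for lvl in self.substitution_levels:
            if not 0 <= lvl <= 100:
                raise ValueError(f"substitution level {lvl} outside [0,100]")
        if self.design == "artemia_supplementation":
            # supplementation rebalances the diet: dose effects vanish
            object.__setattr__(self, "agr_dose_slope", 0.0)
            object.__setattr__(self, "hsi_dose_slope_male", 0.0)
            object.__setattr__(self, "carb_uptake_dose_slope", 0.0)
        for ep in self.endpoints:
            if ep.sex_specific and not isinstance(ep.baseline, dict):
                raise ValueError(f"{ep.name}: sex-specific endpoint needs per-sex baselines")
        for ep_name, shifts in self.arm_shifts.items():
            for arm in shifts:
                if arm not in ("GM", "WT", "NS"):
                    raise ValueError(f"unknown arm {arm!r} in arm_shifts[{ep_name!r}]")
        return self


# --------------------------------------------------------------------------
# substitution dose trial
# --------------------------------------------------------------------------

def _diet_table(config: SimulationConfig) -> pd.DataFrame:
    diets = load_range_finding_diets()
    wanted = [f"sub{int(lvl)}" for lvl in config.substitution_levels]
    keep = diets["diet_id"].isin(wanted)
    if config.include_ccd:
        keep |= diets["diet_id"] == "CCD"
    out = diets[keep].reset_index(drop=True)
    missing = set(wanted) - set(out["diet_id"])
    if missing:
        raise ValueError(
            f"no packaged composition for substitution level(s) {sorted(missing)}; "
            "available levels are 0, 5, 10, 15, 20, 25"
        )
    return out


def generate_substitution_trial(config: SimulationConfig, seed: int) -> TrialDataset:
    """Simulate a maize-substitution dose trial (range finding or *Artemia*).

    Day-0 fish lengths are normal, weights follow W = a·L^b with lognormal
    scatter; each tank grows with AGR = baseline + slope × substitution% +
    tank effect; male HSI carries its own dose slope; fecal masses are
    consistent with the configured apparent-uptake fractions.  The returned
    dataset passes full validation.
    """
    if config.design not in ("range_finding", "artemia_supplementation"):
        raise ValueError(f"design {config.design!r} is not a substitution trial")
    diets = _diet_table(config)
    root = np.random.SeedSequence([seed, 101])
    t = float(config.duration_days)
    n_half = config.n_fish_per_tank // 2

    fish_rows, tank_rows, organ_rows, feces_rows, ration_rows = [], [], [], [], []
    diet_list = list(diets.itertuples(index=False))
    tank_seeds = root.spawn(len(diet_list) * config.n_tanks_per_diet)
    k = 0
    for diet in diet_list:
        sub = 0.0 if diet.is_commercial_control else float(diet.substitution_pct)
        for j in range(config.n_tanks_per_diet):
            tank_id = f"{diet.diet_id}_T{j + 1}"
            tank_rows.append({"tank_id": tank_id, "diet_id": diet.diet_id})
            rng = np.random.default_rng(tank_seeds[k]); k += 1

            sexes = np.array(["male"] * n_half + ["female"] *
                             (config.n_fish_per_tank - n_half))
            L0 = rng.normal(config.length_mean_mm, config.length_sd_mm,
                            config.n_fish_per_tank)
            L0 = np.clip(L0, 5.0, None)
            W0 = (config.allometry_a * L0**config.allometry_b
                  * np.exp(rng.normal(0.0, config.weight_log_sd, L0.size)))
            agr_tank = (config.agr_baseline_mm_day
                        + config.agr_dose_slope * sub
                        + rng.normal(0.0, config.agr_sigma_tank))
            Lf = L0 + agr_tank * t + rng.normal(
                0.0, config.growth_sigma_fish_mm, L0.size)
            Lf = np.clip(Lf, 5.0, None)
            Wf = (config.allometry_a * Lf**config.allometry_b
                  * np.exp(rng.normal(0.0, config.weight_log_sd, L0.size)))
            for i in range(config.n_fish_per_tank):
                fid = f"{tank_id}_F{i + 1}"
                fish_rows.append({"fish_id": fid, "tank_id": tank_id, "day": 0,
                                  "sex": sexes[i], "weight_g": W0[i],
                                  "fork_length_mm": L0[i]})
                fish_rows.append({"fish_id": fid, "tank_id": tank_id,
                                  "day": config.duration_days, "sex": sexes[i],
                                  "weight_g": Wf[i], "fork_length_mm": Lf[i]})

            # pooled organ samples at trial end, one per sex
            for sex in ("male", "female"):
                mask = sexes == sex
                tbw = float(Wf[mask].sum())
                hsi_base = 1.2 if sex == "male" else 2.2
                slope = config.hsi_dose_slope_male if sex == "male" else 0.0
                hsi = (hsi_base + slope * sub) * np.exp(
                    rng.normal(0.0, config.hsi_sigma_tank))
                liver_w = hsi / 100.0 * tbw
                carb = 4.0 * np.exp(rng.normal(0.0, 0.3))
                prot = 12.0 * np.exp(rng.normal(0.0, 0.2))
                lip = 6.0 * np.exp(rng.normal(0.0, 0.3))
                organ_rows.append({"tank_id": tank_id, "sex": sex,
                                   "organ": "liver", "n_fish": int(mask.sum()),
                                   "organ_weight_g": liver_w,
                                   "total_body_weight_g": tbw,
                                   "carbohydrate_mg": carb, "protein_mg": prot,
                                   "lipid_mg": lip})
                muscle_w = 0.05 * tbw
                organ_rows.append({"tank_id": tank_id, "sex": sex,
                                   "organ": "muscle", "n_fish": int(mask.sum()),
                                   "organ_weight_g": muscle_w,
                                   "total_body_weight_g": tbw,
                                   "carbohydrate_mg": 2.0 * np.exp(rng.normal(0, 0.2)),
                                   "protein_mg": muscle_w * 180.0
                                   * np.exp(rng.normal(0, 0.1)),
                                   "lipid_mg": muscle_w * 25.0
                                   * np.exp(rng.normal(0, 0.25))})

            # daily ration (2.5 % of total initial wet weight) and feces
            dose_mg = config.ration_fraction * float(W0.sum()) * 1000.0
            feed = {"carbohydrate": dose_mg * diet.carbohydrates / 100.0,
                    "protein": dose_mg * diet.proteins / 100.0,
                    "lipid": dose_mg * diet.lipids / 100.0}
            ration_rows.append({"tank_id": tank_id,
                                "carbohydrate_mg_day": feed["carbohydrate"],
                                "protein_mg_day": feed["protein"],
                                "lipid_mg_day": feed["lipid"]})
            fec = {}
            for comp, base in config.uptake_baseline_pct.items():
                slope = (config.carb_uptake_dose_slope
                         if comp == "carbohydrate" else 0.0)
                uptake = base + slope * sub + rng.normal(0.0, config.uptake_sigma_tank)
                uptake = float(np.clip(uptake, 1.0, 99.5))
                fec[comp] = feed[comp] * (1.0 - uptake / 100.0)
            feces_rows.append({"tank_id": tank_id, "collection_hours": 24.0,
                               "carbohydrate_mg": fec["carbohydrate"],
                               "protein_mg": fec["protein"],
                               "lipid_mg": fec["lipid"]})

    return TrialDataset(
        trial_id=config.design,
        fish=pd.DataFrame(fish_rows),
        tanks=pd.DataFrame(tank_rows),
        diets=diets,
        organs=pd.DataFrame(organ_rows),
        feces=pd.DataFrame(feces_rows),
        rations=pd.DataFrame(ration_rows),
        control_diet_id="sub0",
        schedule=(0, config.duration_days),
    )


# --------------------------------------------------------------------------
# natural response variation
# --------------------------------------------------------------------------

def generate_reference_dataset(config: SimulationConfig, seed: int):
    """Simulate the multi-variety reference trial for every configured endpoint.

    Variety, trial and tank effects are drawn on each endpoint's link scale
    with the configured SDs; fish-level endpoints add per-fish scatter.
    Returns a validated
    :class:`~gmtrial.equivalence.ReferenceVariationDataset`.
    """
    from .equivalence import ReferenceVariationDataset

    if config.design != "natural_variation":
        raise ValueError("design must be 'natural_variation'")
    root = np.random.SeedSequence([seed, 202])
    rows = []
    ep_seeds = root.spawn(len(config.endpoints))
    for ep, ep_seed in zip(config.endpoints, ep_seeds):
        rng = np.random.default_rng(ep_seed)
        for stratum in ep.strata():
            eta0 = ep.link(stratum)
            for trial_i in range(config.n_trials):
                trial_id = f"NRV{trial_i + 1}"
                trial_eff = rng.normal(0.0, ep.sigma_trial) if ep.sigma_trial else 0.0
                for v in range(config.n_varieties):
                    variety = f"MV{v + 1}"
                    var_eff = rng.normal(0.0, ep.sigma_variety)
                    for j in range(config.n_tanks_per_diet):
                        tank_id = f"{variety}_T{j + 1}"
                        tank_eff = rng.normal(0.0, ep.sigma_tank)
                        eta = eta0 + trial_eff + var_eff + tank_eff
                        if ep.level == "fish":
                            vals = ep.from_link(
                                eta + rng.normal(0.0, ep.sigma_fish,
                                                 config.n_fish_per_tank)
                            )
                        else:
                            vals = np.atleast_1d(ep.from_link(eta, rng=rng))
                        for val in np.atleast_1d(vals):
                            rows.append({
                                "endpoint_name": ep.name,
                                "variety_id": variety,
                                "trial_id": trial_id,
                                "tank_id": tank_id,
                                "sex_stratum": stratum,
                                "value": float(val),
                            })
    return ReferenceVariationDataset(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# GM / WT / NS case study
# --------------------------------------------------------------------------

def generate_equivalence_case_study(config: SimulationConfig, seed: int) -> EndpointTable:
    """Simulate the three-arm GM / wild-type / null-segregant trial.

    All three arms share the reference endpoint model (near-isogenic
    material: no variety-level draw separates them); configured
    ``arm_shifts`` displace an arm's mean by the given number of EL units
    (multiples of the endpoint's between-variety SD on its link scale).  A
    shift shared by GM and NS but absent in WT emulates a transformation-
    process effect; a GM-only shift emulates a transgene effect.  Returns
    tank-level endpoint values as an :class:`~gmtrial.endpoints.EndpointTable`.
    """
    if config.design != "equivalence_case_study":
        raise ValueError("design must be 'equivalence_case_study'")
    root = np.random.SeedSequence([seed, 303])
    rows = []
    ep_seeds = root.spawn(len(config.endpoints))
    day = config.duration_days
    for ep, ep_seed in zip(config.endpoints, ep_seeds):
        rng = np.random.default_rng(ep_seed)
        shifts = config.arm_shifts.get(ep.name, {})
        for stratum in ep.strata():
            eta0 = ep.link(stratum)
            for arm in ("GM", "WT", "NS"):
                arm_eta = eta0 + shifts.get(arm, 0.0) * ep.sigma_variety
                for j in range(config.n_tanks_per_diet):
                    tank_id = f"{arm}_T{j + 1}"
                    eta = arm_eta + rng.normal(0.0, ep.sigma_tank)
                    val = float(np.atleast_1d(ep.from_link(eta, rng=rng))[0])
                    rows.append({
                        "trial_id": "case_study",
                        "diet_id": arm,
                        "tank_id": tank_id,
                        "sex_stratum": stratum,
                        "endpoint_name": ep.name,
                        "day": day,
                        "value": val,
                    })
    return EndpointTable(pd.DataFrame(rows, columns=ENDPOINT_COLUMNS))
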
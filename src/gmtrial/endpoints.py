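"""Physiological and dietary endpoints of a zebrafish feeding trial.

Covers the length–weight allometry W = a·L^b, the relative condition factor
RCF = W/(a·L^b), the absolute growth rate AGR = (L_f − L_i)/t on tank-mean
fork lengths, hepato-/gonadosomatic indices from pooled organ samples, gross
dietary energy from macronutrient composition, coefficients of variation,
and apparent nutrient uptake from the feed/feces mass balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import (
    DietComposition,
    FecalSample,
    FeedRation,
    PooledOrganSample,
    TrialDataset,
    ENDPOINT_COLUMNS,
)

__all__ = [
    "LengthWeightModel",
    "EndpointTable",
    "GROSS_ENERGY_KJ_PER_G",
    "fit_length_weight",
    "compute_rcf",
    "compute_agr",
    "compute_somatic_index",
    "compute_gross_energy",
    "compute_cv",
    "compute_nutrient_uptake",
    "build_endpoint_table",
    "diet_composition_report",
    "load_range_finding_diets",
    "load_reference_variety_diets",
    "InsufficientDataError",
    "DegenerateFitError",
]

log = logging.getLogger(__name__)

#: Gross energy coefficients, kJ per g of macronutrient.
GROSS_ENERGY_KJ_PER_G = {"carbohydrates": 17.5, "proteins": 24.0, "lipids": 39.5}


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit or summary."""


class DegenerateFitError(ValueError):
    """The design matrix has no variation; the fit is undefined."""


# --------------------------------------------------------------------------
# length-weight allometry and condition factor
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthWeightModel:
    """Allometric length–weight relationship W = a·L^b.

    Fitted by least squares on log-transformed data (multiplicative error
    model, standard fisheries practice).  ``a`` is in g·mm^−b, ``b`` is
    dimensionless; exponents far outside 2–4 are flagged, not rejected.
    """

    a: float
    b: float
    n_fish: int
    fit_day: int

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"coefficient a must be > 0, got {self.a}")
        if not (2.0 < self.b < 4.0):
            log.warning(
                "allometric exponent b=%.3f outside the usual 2-4 range", self.b
            )

    def predicted_weight(self, fork_length_mm):
        return self.a * np.asarray(fork_length_mm, dtype=float) ** self.b


def fit_length_weight(fish: pd.DataFrame, day: int | None = None) -> LengthWeightModel:
    """Fit W = a·L^b to all fish at one day by log-log linear regression.

    ``fish`` is a fish table (``weight_g``, ``fork_length_mm``, ``day``); if
    ``day`` is None all rows must share one day.  Needs ≥ 10 fish and
    variation in length.
    """
    if day is not None:
        fish = fish[fish["day"] == day]
    days = fish["day"].unique()
    if len(days) > 1:
        raise ValueError(f"fish span several days {sorted(days)}; pass day= explicitly")
    if len(fish) < 10:
        raise InsufficientDataError(
            f"need >= 10 fish to fit the length-weight curve, got {len(fish)}"
        )
    L = fish["fork_length_mm"].to_numpy(dtype=float)
    W = fish["weight_g"].to_numpy(dtype=float)
    logL = np.log(L)
    if np.ptp(logL) == 0.0:
        raise DegenerateFitError("all fish share one fork length; slope undefined")
    res = stats.linregress(logL, np.log(W))
    return LengthWeightModel(
        a=float(np.exp(res.intercept)),
        b=float(res.slope),
        n_fish=int(len(fish)),
        fit_day=int(days[0]),
    )


def compute_rcf(weight_g, fork_length_mm, model: LengthWeightModel):
    """Relative condition factor RCF = W / (a·L^b); 1 means on-curve."""
    W = np.asarray(weight_g, dtype=float)
    return W / model.predicted_weight(fork_length_mm)


# --------------------------------------------------------------------------
# growth and somatic indices
# --------------------------------------------------------------------------

def compute_agr(initial_lengths_mm, final_lengths_mm, t_days: float) -> float:
    """Absolute growth rate (mm/day) from tank-mean fork lengths.

    AGR = (mean final − mean initial) / t; the statistical unit is the tank.
    """
    if t_days <= 0:
        raise ValueError(f"elapsed time must be positive, got {t_days}")
    Li = np.asarray(initial_lengths_mm, dtype=float)
    Lf = np.asarray(final_lengths_mm, dtype=float)
    if Li.size == 0 or Lf.size == 0:
        raise InsufficientDataError("both length sets must be non-empty")
    return float((Lf.mean() - Li.mean()) / t_days)


def compute_somatic_index(organ: PooledOrganSample) -> float:
    """Somatic index (%): 100 × pooled organ weight / summed body weight."""
    return 100.0 * organ.organ_weight / organ.total_body_weight


# --------------------------------------------------------------------------
# diet energetics
# --------------------------------------------------------------------------

def compute_gross_energy(diet) -> float:
    """Gross energy (kJ/g diet) as a fixed linear combination of macronutrients.

    Uses 17.5 kJ/g for carbohydrates, 24 kJ/g for proteins and 39.5 kJ/g for
    lipids on a g/100 g composition.  ``diet`` may be a
    :class:`~gmtrial.core_model.DietComposition` or any object/row with
    ``carbohydrates``, ``proteins`` and ``lipids`` attributes or keys.
    """
    if isinstance(diet, (pd.Series, dict)):
        C, P, Lp = diet["carbohydrates"], diet["proteins"], diet["lipids"]
    else:
        C, P, Lp = diet.carbohydrates, diet.proteins, diet.lipids
    g = GROSS_ENERGY_KJ_PER_G
    return (g["carbohydrates"] * C + g["proteins"] * P + g["lipids"] * Lp) / 100.0


def compute_cv(values) -> float:
    """Coefficient of variation (%): 100 × sample SD (n−1) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"CV needs >= 2 values, got {x.size}")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / m)


def _round1(x: float) -> float:
    """Half-up rounding to one decimal, as in printed composition tables."""
    return float(np.floor(x * 10.0 + 0.5) / 10.0)


def load_range_finding_diets() -> pd.DataFrame:
    """Macronutrient compositions of the CCD and the 0–25 % substitution diets."""
    with resources.files("gmtrial.data").joinpath("range_finding_diets.csv").open() as f:
        return pd.read_csv(f)


def load_reference_variety_diets() -> pd.DataFrame:
    """Compositions of the ten 15 %-substitution reference-variety diets."""
    with resources.files("gmtrial.data").joinpath("reference_variety_diets.csv").open() as f:
        return pd.read_csv(f)


def diet_composition_report(diets: pd.DataFrame) -> pd.DataFrame:
    """Composition summary mirroring the published diet tables.

    One column per diet plus a CV column over the experimental (non-CCD)
    diets; rows are dry matter, the three macronutrients and the computed
    gross energy.  Gross-energy cells are rounded to one decimal and the
    gross-energy CV is computed from those rounded values, matching how the
    printed tables display the energy row.
    """
    diets = diets.reset_index(drop=True)
    experimental = diets[~diets["is_commercial_control"].astype(bool)]
    rows = {}
    for row_name, col in (
        ("dry_matter", "dry_matter"),
        ("carbohydrates", "carbohydrates"),
        ("proteins", "proteins"),
        ("lipids", "lipids"),
    ):
        rows[row_name] = {
            d.diet_id: getattr(d, col) for d in diets.itertuples(index=False)
        }
        rows[row_name]["CV_pct"] = _round1(compute_cv(experimental[col]))
    ge = {d.diet_id: _round1(compute_gross_energy(d)) for d in diets.itertuples(index=False)}
    ge_exp = [ge[d] for d in experimental["diet_id"]]
    ge["CV_pct"] = _round1(compute_cv(ge_exp))
    rows["gross_energy_kj_g"] = ge
    return pd.DataFrame(rows).T


# --------------------------------------------------------------------------
# nutrient uptake (apparent digestibility)
# --------------------------------------------------------------------------

def compute_nutrient_uptake(
    ration: FeedRation, feces: FecalSample
) -> dict[str, dict[str, float]]:
    """Apparent nutrient uptake (%) per macronutrient from the feed/feces balance.

    uptake = 100 × (1 − fecal mass / one-day feed mass).  The raw
    feces-to-feed ratio is also returned for transparency.  A fecal mass
    exceeding the feed mass yields a negative uptake and a logged flag.
    """
    out: dict[str, dict[str, float]] = {}
    for comp, feed_mass in ration.component_mass_per_day.items():
        fecal_mass = feces.component_mass.get(comp)
        if fecal_mass is None or np.isnan(fecal_mass):
            continue
        if feed_mass == 0:
            if fecal_mass > 0:
                raise ValueError(
                    f"{comp}: fecal mass {fecal_mass} mg with zero feed mass"
                )
            continue
        ratio = fecal_mass / feed_mass
        uptake = 100.0 * (1.0 - ratio)
        if uptake < 0:
            log.warning(
                "tank %s: fecal %s mass exceeds the daily feed mass "
                "(uptake %.1f%%)", feces.tank_id, comp, uptake,
            )
        out[comp] = {"uptake_pct": uptake, "feces_to_feed_ratio": ratio}
    return out


# --------------------------------------------------------------------------
# endpoint table assembly
# --------------------------------------------------------------------------

@dataclass
class EndpointTable:
    """Replicate-level endpoint values — the statistical unit of the analysis.

    ``frame`` has one row per (trial, diet, tank, sex-stratum, endpoint, day);
    values are finite or missing.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ENDPOINT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"endpoint table missing column(s): {missing}")
        key = ["tank_id", "sex_stratum", "endpoint_name", "day"]
        if self.frame.duplicated(subset=key).any():
            raise ValueError("duplicate (tank, stratum, endpoint, day) rows")

    def values_by_diet(
        self, endpoint: str, sex_stratum: str | None = None, day: int | None = None
    ) -> dict[str, np.ndarray]:
        """Tank values per diet for one endpoint (and optional stratum/day)."""
        sel = self.frame[self.frame["endpoint_name"] == endpoint]
        if sex_stratum is not None:
            sel = sel[sel["sex_stratum"] == sex_stratum]
        if day is not None:
            sel = sel[sel["day"] == day]
        sel = sel.dropna(subset=["value"])
        return {
            diet: grp["value"].to_numpy(dtype=float)
            for diet, grp in sel.groupby("diet_id", sort=True)
        }

    def endpoints(self) -> list[str]:
        return sorted(self.frame["endpoint_name"].unique())

    def __len__(self) -> int:
        return len(self.frame)


def build_endpoint_table(
    trial: TrialDataset, model: LengthWeightModel
) -> EndpointTable:
    """Derive every computable endpoint of a trial at its scheduled days.

    Emits per-tank RCF and length means at every measured day, AGR from the
    first to the last measurement day, HSI/GSI per sex, apparent nutrient
    uptake per macronutrient, and organ energy-reserve concentrations
    (mg per g tissue) plus absolute pooled contents (mg per pooled sample).
    Endpoints whose inputs are missing are omitted, never imputed.
    """
    if model.fit_day != (min(trial.schedule) if trial.schedule else 0):
        if trial.schedule and model.fit_day not in trial.schedule:
            raise ValueError(
                f"length-weight model fitted on day {model.fit_day}, which is "
                f"not in the trial schedule {trial.schedule}"
            )
    tank_diet = trial.tank_to_diet()
    rows: list[dict] = []

    def add(tank, stratum, endpoint, value, day):
        rows.append(
            {
                "trial_id": trial.trial_id,
                "diet_id": tank_diet[tank],
                "tank_id": tank,
                "sex_stratum": stratum,
                "endpoint_name": endpoint,
                "day": day,
                "value": value,
            }
        )

    fish = trial.fish
    days = sorted(fish["day"].unique()) if len(fish) else []
    for day in days:
        at_day = fish[fish["day"] == day]
        rcf = compute_rcf(at_day["weight_g"], at_day["fork_length_mm"], model)
        at_day = at_day.assign(_rcf=rcf)
        for tank, grp in at_day.groupby("tank_id"):
            add(tank, "pooled", "RCF", float(grp["_rcf"].mean()), int(day))
            add(tank, "pooled", "length", float(grp["fork_length_mm"].mean()), int(day))

    if len(days) >= 2:
        d0, d1 = days[0], days[-1]
        t = float(d1 - d0)
        for tank in trial.tanks["tank_id"]:
            Li = fish[(fish["day"] == d0) & (fish["tank_id"] == tank)]["fork_length_mm"]
            Lf = fish[(fish["day"] == d1) & (fish["tank_id"] == tank)]["fork_length_mm"]
            if len(Li) and len(Lf):
                add(tank, "pooled", "AGR", compute_agr(Li, Lf, t), int(d1))

    index_name = {"liver": "HSI", "gonad": "GSI"}
    organ_prefix = {"liver": "liver", "gonad": "gonad", "muscle": "muscle"}
    comp_cols = {"carbohydrate": "carbohydrate_mg", "protein": "protein_mg", "lipid": "lipid_mg"}
    end_day = int(days[-1]) if days else 0
    for row in trial.organs.itertuples(index=False):
        sample = PooledOrganSample(
            tank_id=row.tank_id,
            sex=row.sex,
            organ=row.organ,
            n_fish=int(row.n_fish),
            organ_weight=float(row.organ_weight_g),
            total_body_weight=float(row.total_body_weight_g),
        )
        if row.organ in index_name:
            add(row.tank_id, row.sex, index_name[row.organ],
                compute_somatic_index(sample), end_day)
        prefix = organ_prefix[row.organ]
        for comp, col in comp_cols.items():
            mass_mg = getattr(row, col)
            if mass_mg is None or (isinstance(mass_mg, float) and np.isnan(mass_mg)):
                continue
            # concentration in mg per g of tissue, plus absolute pooled content
            if sample.organ_weight > 0:
                add(row.tank_id, row.sex, f"{prefix}_{comp}_conc",
                    float(mass_mg) / (sample.organ_weight), end_day)
            add(row.tank_id, row.sex, f"{prefix}_{comp}_content",
                float(mass_mg), end_day)

    if len(trial.feces) and len(trial.rations):
        rations = {r.tank_id: r for r in trial.rations.itertuples(index=False)}
        for row in trial.feces.itertuples(index=False):
            if row.tank_id not in rations:
                continue
            r = rations[row.tank_id]
            ration = FeedRation(
                tank_id=row.tank_id,
                component_mass_per_day={
                    "carbohydrate": float(r.carbohydrate_mg_day),
                    "protein": float(r.protein_mg_day),
                    "lipid": float(r.lipid_mg_day),
                },
            )
            feces = FecalSample(
                tank_id=row.tank_id,
                collection_hours=float(row.collection_hours),
                component_mass={
                    "carbohydrate": float(row.carbohydrate_mg),
                    "protein": float(row.protein_mg),
                    "lipid": float(row.lipid_mg),
                },
            )
            for comp, res in compute_nutrient_uptake(ration, feces).items():
                add(row.tank_id, "pooled", f"uptake_{comp}", res["uptake_pct"], end_day)
    elif len(trial.feces) or len(trial.rations):
        log.info(
            "trial %s: feces or rations missing; uptake endpoints omitted",
            trial.trial_id,
        )

    frame = pd.DataFrame(rows, columns=ENDPOINT_COLUMNS)
    return EndpointTable(frame)
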
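"""Distribution-wise equivalence (DWE) testing against natural response variation.

A potential effect of a GM feed component is judged against the *natural
response variation*: the spread of each endpoint across feeding groups given
different non-GM reference varieties of the same crop.  The workflow is:

1. estimate variance components (variety, trial, tank, residual) of the
   reference dataset by REML for each endpoint;
2. derive an endpoint-specific equivalence limit
   ``EL = multiplier × sqrt(sigma2_variety + sigma2_trial)`` — the SD of
   endpoint means across reference populations (a fixed one-sample-SD
   alternative is available for comparison);
3. express the test-vs-control mean difference in EL units with a 95 %
   confidence interval from the between-tank variance;
4. classify each contrast: *proof of equivalence* when the whole CI lies in
   (−1, +1), *equivalence more likely than not* when only the point estimate
   does, *equivalence not likely* when the estimate is outside but the CI
   overlaps the limits, and *proof of non-equivalence* when the CI is
   entirely outside.  Failure to demonstrate equivalence is never proof of
   non-equivalence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceVariationDataset",
    "VarianceComponents",
    "EquivalenceResult",
    "CONTRASTS",
    "DEFAULT_CASE_STUDY_ENDPOINTS",
    "VERDICTS",
    "fit_reference_variance_components",
    "compute_equivalence_limit",
    "scaled_difference",
    "classify_equivalence",
    "equivalence_report",
    "DegenerateLimitError",
    "InsufficientReferenceError",
]

log = logging.getLogger(__name__)

CONTRASTS = ("GM_vs_NS", "GM_vs_WT", "NS_vs_WT")
VERDICTS = (
    "proof_of_equivalence",
    "equivalence_more_likely_than_not",
    "equivalence_not_likely",
    "proof_of_non_equivalence",
)
#: Endpoints of the published forest plot: adult length, hepatosomatic index,
#: liver carbohydrate and protein contents, gonadosomatic index.
DEFAULT_CASE_STUDY_ENDPOINTS = (
    "length_adult",
    "HSI",
    "liver_carbohydrate_content",
    "liver_protein_content",
    "GSI",
)

REFERENCE_COLUMNS = [
    "endpoint_name",
    "variety_id",
    "trial_id",
    "tank_id",
    "sex_stratum",
    "value",
]


class InsufficientReferenceError(ValueError):
    """Fewer than three reference varieties for an endpoint."""


class DegenerateLimitError(ValueError):
    """No between-population reference variation; the DWE limit is zero."""


# --------------------------------------------------------------------------
# reference dataset
# --------------------------------------------------------------------------

@dataclass
class ReferenceVariationDataset:
    """Endpoint values recorded across non-GM reference varieties.

    One row per measurement: (endpoint, variety, trial, tank, sex-stratum,
    value).  Requires at least 3 varieties per endpoint and 2 tanks per
    variety.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REFERENCE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"reference dataset missing column(s): {missing}")
        for endpoint, grp in self.frame.groupby("endpoint_name"):
            if grp["variety_id"].nunique() < 3:
                raise InsufficientReferenceError(
                    f"endpoint {endpoint!r} covers "
                    f"{grp['variety_id'].nunique()} varieties; need >= 3"
                )
            tanks_per_variety = grp.groupby("variety_id")["tank_id"].nunique()
            if tanks_per_variety.min() < 2:
                raise InsufficientReferenceError(
                    f"endpoint {endpoint!r}: every variety needs >= 2 tanks"
                )

    def endpoints(self) -> list[str]:
        return sorted(self.frame["endpoint_name"].unique())

    def subset(self, endpoint: str, sex_stratum: str | None = None) -> pd.DataFrame:
        sel = self.frame[self.frame["endpoint_name"] == endpoint]
        if sex_stratum is not None:
            sel = sel[sel["sex_stratum"] == sex_stratum]
        return sel.dropna(subset=["value"])

    @classmethod
    def read_csv(cls, path) -> "ReferenceVariationDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame[REFERENCE_COLUMNS].to_csv(path, index=False)


# --------------------------------------------------------------------------
# variance components
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    """REML variance decomposition of one endpoint's reference variation."""

    endpoint_name: str
    grand_mean: float
    sigma2_variety: float
    sigma2_trial: float
    sigma2_tank: float
    sigma2_residual: float
    n_varieties: int
    n_trials: int
    n_tanks: int
    trial_confounded: bool = False

    @property
    def total_variance(self) -> float:
        return (
            self.sigma2_variety
            + self.sigma2_trial
            + self.sigma2_tank
            + self.sigma2_residual
        )


def _fit_reml(model):
    # Powell with tight tolerances reliably finds the REML optimum for these
    # small variance-component models (gradient methods can stall at a
    # boundary-ish point); gradient methods are the fallback.
    try:
        res = model.fit(reml=True, method=["powell"], maxiter=5000,
                        xtol=1e-12, ftol=1e-12)
        if res.converged:
            return res
    except Exception:  # pragma: no cover
        pass
    return model.fit(reml=True, method=["cg", "lbfgs"])


def _is_tank_level(frame: pd.DataFrame) -> bool:
    per_tank = frame.groupby(["trial_id", "tank_id"]).size()
    return bool((per_tank <= 1).all())


def fit_reference_variance_components(
    ref: ReferenceVariationDataset | pd.DataFrame,
    endpoint: str,
    sex_stratum: str | None = None,
) -> VarianceComponents:
    """REML fit of value = μ + variety + trial + tank(variety×trial) + ε.

    Random effects are independent and zero-mean; REML keeps every component
    non-negative (boundary estimates are reported as 0 and logged).  With a
    single feeding trial the trial component is inestimable — it is reported
    as 0 with ``trial_confounded=True``.  Tank-level endpoints (one value per
    tank) report the between-tank variance as ``sigma2_tank`` and
    ``sigma2_residual = 0``.
    """
    import statsmodels.formula.api as smf

    frame = ref.subset(endpoint, sex_stratum) if isinstance(
        ref, ReferenceVariationDataset
    ) else ref
    if frame["variety_id"].nunique() < 3:
        raise InsufficientReferenceError(
            f"endpoint {endpoint!r}: need >= 3 reference varieties"
        )
    data = frame.copy()
    data["value"] = data["value"].astype(float)
    n_varieties = data["variety_id"].nunique()
    n_trials = data["trial_id"].nunique()
    n_tanks = data.groupby(["trial_id", "tank_id"]).ngroups
    grand_mean = float(data["value"].mean())
    tank_level = _is_tank_level(data)

    if np.ptp(data["value"].to_numpy()) == 0.0:
        log.warning("endpoint %s: all reference values identical", endpoint)
        return VarianceComponents(endpoint, grand_mean, 0.0, 0.0, 0.0, 0.0,
                                  n_varieties, n_trials, n_tanks,
                                  trial_confounded=n_trials == 1)

    # unique tank labels across trials so C(tank_uid) nests correctly
    data["tank_uid"] = data["trial_id"].astype(str) + ":" + data["tank_id"].astype(str)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n_trials == 1:
            if tank_level:
                model = smf.mixedlm("value ~ 1", data, groups=data["variety_id"])
                res = _fit_reml(model)
                s2v = float(res.cov_re.iloc[0, 0])
                s2tank = float(res.scale)
                s2resid = 0.0
            else:
                model = smf.mixedlm(
                    "value ~ 1",
                    data,
                    groups=data["variety_id"],
                    re_formula="1",
                    vc_formula={"tank": "0 + C(tank_uid)"},
                )
                res = _fit_reml(model)
                s2v = float(res.cov_re.iloc[0, 0])
                s2tank = float(res.vcomp[0])
                s2resid = float(res.scale)
            s2trial = 0.0
            confounded = True
        else:
            # crossed variety x trial random effects via the single-group trick
            data["_all"] = 1
            vc = {
                "variety": "0 + C(variety_id)",
                "trial": "0 + C(trial_id)",
            }
            if not tank_level:
                vc["tank"] = "0 + C(tank_uid)"
            model = smf.mixedlm(
                "value ~ 1", data, groups=data["_all"], vc_formula=vc
            )
            res = _fit_reml(model)
            names = list(model.exog_vc.names)
            vcomp = dict(zip(names, res.vcomp))
            s2v = float(vcomp["variety"])
            s2trial = float(vcomp["trial"])
            if tank_level:
                s2tank = float(res.scale)
                s2resid = 0.0
            else:
                s2tank = float(vcomp["tank"])
                s2resid = float(res.scale)
            confounded = False

    comps = {"variety": s2v, "trial": s2trial, "tank": s2tank}
    for name, v in comps.items():
        if v < 0:
            log.warning("endpoint %s: %s variance truncated at 0", endpoint, name)
            comps[name] = 0.0
    return VarianceComponents(
        endpoint_name=endpoint,
        grand_mean=grand_mean,
        sigma2_variety=comps["variety"],
        sigma2_trial=comps["trial"],
        sigma2_tank=comps["tank"],
        sigma2_residual=max(s2resid, 0.0),
        n_varieties=n_varieties,
        n_trials=n_trials,
        n_tanks=n_tanks,
        trial_confounded=confounded,
    )


# --------------------------------------------------------------------------
# equivalence limit
# --------------------------------------------------------------------------

def compute_equivalence_limit(
    vc: VarianceComponents,
    multiplier: float = 1.0,
    mode: str = "dwe",
    reference_values=None,
) -> float:
    """Equivalence limit on the endpoint's natural scale.

    ``dwe`` mode (default): EL = multiplier × sqrt(σ²_variety + σ²_trial),
    the SD of endpoint means across reference populations.  ``fixed`` mode:
    EL = one sample SD of the raw reference values (the fixed-limit
    convention), for which ``reference_values`` must be supplied.
    """
    if mode == "dwe":
        el = multiplier * float(np.sqrt(vc.sigma2_variety + vc.sigma2_trial))
        if el <= 0:
            raise DegenerateLimitError(
                f"endpoint {vc.endpoint_name!r}: no between-population reference "
                "variation; consider mode='fixed' (one sample SD)"
            )
        return el
    if mode == "fixed":
        if reference_values is None:
            raise ValueError("fixed mode needs the raw reference values")
        x = np.asarray(reference_values, dtype=float)
        el = multiplier * float(x.std(ddof=1))
        if el <= 0:
            raise DegenerateLimitError("reference values have zero spread")
        return el
    raise ValueError(f"unknown EL mode {mode!r}")


# --------------------------------------------------------------------------
# scaled difference and classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EquivalenceResult:
    """EL-scaled mean difference with CI and categorical verdict.

    ``scaled_estimate`` is (mean_test − mean_control)/EL; the verdict follows
    the (−1, +1) interval rule.  Non-proof of equivalence is *not* proof of
    non-equivalence.
    """

    endpoint_name: str
    contrast: str
    scaled_estimate: float
    ci_low: float
    ci_high: float
    el_absolute: float
    sex_stratum: str = "pooled"
    verdict: str | None = None
    df: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.scaled_estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def scaled_difference(
    test_values,
    control_values,
    el_absolute: float,
    vc: VarianceComponents | None = None,
    satterthwaite: bool = False,
    conf_level: float = 0.95,
    endpoint_name: str = "",
    contrast: str = "",
    sex_stratum: str = "pooled",
) -> EquivalenceResult:
    """EL-scaled mean difference between two groups of tank values.

    The SE comes from the pooled between-tank variance of the two groups
    with n₁+n₂−2 degrees of freedom.  With ``satterthwaite=True`` and a
    fitted ``vc``, the uncertainty of the reference-derived EL (delta-method
    variance of an SD estimated from n_varieties populations) is folded into
    the interval via a Satterthwaite effective df; the default treats the EL
    as a fixed scale, which is the conventional reading of an EL-scaled
    forest plot.
    """
    if el_absolute <= 0:
        raise ValueError(f"el_absolute must be > 0, got {el_absolute}")
    a = np.asarray(test_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 tanks")
    diff = a.mean() - b.mean()
    df = a.size + b.size - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    est = diff / el_absolute
    se_scaled = se / el_absolute

    df_eff = float(df)
    if satterthwaite and vc is not None and vc.n_varieties > 1:
        # delta-method variance of the scaled estimate from EL estimation:
        # var(EL_hat)/EL^2 ~ 1/(2 (n_varieties - 1)) for an SD from
        # n_varieties population means
        v1 = se_scaled**2
        v2 = est**2 / (2.0 * (vc.n_varieties - 1))
        if v1 + v2 > 0 and v2 > 0:
            df_eff = (v1 + v2) ** 2 / (
                v1**2 / df + v2**2 / (vc.n_varieties - 1)
            )
            se_scaled = np.sqrt(v1 + v2)

    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, df_eff)
    half = tcrit * se_scaled
    return EquivalenceResult(
        endpoint_name=endpoint_name,
        contrast=contrast,
        scaled_estimate=float(est),
        ci_low=float(est - half),
        ci_high=float(est + half),
        el_absolute=float(el_absolute),
        sex_stratum=sex_stratum,
        df=df_eff,
    )


def classify_equivalence(result: EquivalenceResult) -> EquivalenceResult:
    """Attach the categorical verdict from the (−1, +1) interval rule."""
    lo, hi, est = result.ci_low, result.ci_high, result.scaled_estimate
    if lo > 1.0 or hi < -1.0:
        verdict = "proof_of_non_equivalence"
    elif abs(est) < 1.0:
        if lo > -1.0 and hi < 1.0:
            verdict = "proof_of_equivalence"
        else:
            verdict = "equivalence_more_likely_than_not"
    else:
        verdict = "equivalence_not_likely"
    return replace(result, verdict=verdict)


# --------------------------------------------------------------------------
# full report
# --------------------------------------------------------------------------

def equivalence_report(
    endpoint_table,
    ref: ReferenceVariationDataset,
    endpoints=None,
    arms: dict[str, str] | None = None,
    el_multiplier: float = 1.0,
    el_mode: str = "dwe",
    satterthwaite: bool = False,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Equivalence of GM vs NS, GM vs WT and NS vs WT for a set of endpoints.

    ``endpoint_table`` holds tank-level values for the three arms (diet ids
    "GM", "WT", "NS" unless remapped through ``arms``).  For every endpoint ×
    sex-stratum × contrast one classified :class:`EquivalenceResult` row is
    emitted, with the EL derived from the reference dataset for that same
    endpoint and stratum.  Endpoints that fail (e.g. absent from the
    reference data) are reported with an ``error`` column; the others are
    still computed.  When the reference data come from a single trial the
    trial variance is confounded with variety and the EL rests on the
    variety component alone; this limitation is logged.
    """
    arms = arms or {"GM": "GM", "WT": "WT", "NS": "NS"}
    endpoints = list(endpoints) if endpoints is not None else [
        e for e in DEFAULT_CASE_STUDY_ENDPOINTS
        if e in endpoint_table.endpoints()
    ]
    rows = []
    for endpoint in endpoints:
        ref_strata = sorted(
            ref.frame.loc[
                ref.frame["endpoint_name"] == endpoint, "sex_stratum"
            ].unique()
        ) or ["pooled"]
        for stratum in ref_strata:
            try:
                vc = fit_reference_variance_components(ref, endpoint, stratum)
                if vc.trial_confounded:
                    log.info(
                        "endpoint %s: reference data from a single trial; "
                        "trial variance confounded with variety, EL based on "
                        "the variety component alone", endpoint,
                    )
                el = compute_equivalence_limit(
                    vc, multiplier=el_multiplier, mode=el_mode,
                    reference_values=ref.subset(endpoint, stratum)["value"],
                )
                groups = endpoint_table.values_by_diet(endpoint, stratum)
                for contrast in CONTRASTS:
                    t_arm, c_arm = contrast.split("_vs_")
                    tv = groups.get(arms[t_arm])
                    cv = groups.get(arms[c_arm])
                    if tv is None or cv is None:
                        raise ValueError(
                            f"missing arm for contrast {contrast} "
                            f"(have {sorted(groups)})"
                        )
                    res = classify_equivalence(
                        scaled_difference(
                            tv, cv, el, vc=vc, satterthwaite=satterthwaite,
                            conf_level=conf_level, endpoint_name=endpoint,
                            contrast=contrast, sex_stratum=stratum,
                        )
                    )
                    rows.append(
                        {
                            "endpoint_name": endpoint,
                            "sex_stratum": stratum,
                            "contrast": contrast,
                            "scaled_estimate": res.scaled_estimate,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "el_absolute": res.el_absolute,
                            "verdict": res.verdict,
                            "error": "",
                        }
                    )
            except Exception as exc:  # partial-failure contract
                log.warning("endpoint %s (%s): %s", endpoint, stratum, exc)
                rows.append(
                    {
                        "endpoint_name": endpoint,
                        "sex_stratum": stratum,
                        "contrast": "",
                        "scaled_estimate": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "el_absolute": np.nan,
                        "verdict": "",
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)


def forest_plot(report: pd.DataFrame, path=None):
    """Forest plot of EL-scaled differences with the ±1 EL lines.

    Requires matplotlib (optional dependency).  Returns the figure; saves it
    when ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = report[report["error"] == ""].reset_index(drop=True)
    labels = [
        f"{r.endpoint_name} [{r.sex_stratum}] {r.contrast}"
        for r in ok.itertuples(index=False)
    ]
    y = np.arange(len(ok))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(ok) + 1.5))
    ax.errorbar(
        ok["scaled_estimate"], y,
        xerr=[ok["scaled_estimate"] - ok["ci_low"],
              ok["ci_high"] - ok["scaled_estimate"]],
        fmt="o", color="black", capsize=3,
    )
    ax.axvline(-1.0, color="red")
    ax.axvline(1.0, color="red")
    ax.axvline(0.0, color="grey", linestyle=":")
    ax.set_yticks(y, labels)
    ax.set_xlabel("EL-scaled difference (95% CI)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
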
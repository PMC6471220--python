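"""Conventional group statistics for feeding trials with nested replicates.

The tank (housing unit of 20 fish) is the biological replicate and the
experimental unit.  Replicate-level endpoints (AGR, somatic indices, uptake)
are tested by one-way ANOVA on tank values; individual-level endpoints (RCF,
length) by a mixed one-way ANOVA with the tank nested in the diet as a
random factor.  Many-to-one comparisons against the 0 %-substitution diet
use Dunnett's test with adjusted p-values from the joint multivariate-t
distribution of the correlated contrasts, evaluated by deterministic
quadrature; dose relationships use Pearson correlation; the formulation
check against the commercial control diet uses an unpaired pooled-variance
t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "AnovaResult",
    "DunnettComparison",
    "DunnettResult",
    "CorrelationResult",
    "TTestResult",
    "anova_replicate_level",
    "anova_nested",
    "dunnett_vs_control",
    "dunnett_max_abs_t_cdf",
    "dunnett_critical_value",
    "dose_correlation",
    "ccd_comparison",
    "InsufficientReplicationError",
]

log = logging.getLogger(__name__)

ALPHA = 0.05  # study-wide significance threshold


class InsufficientReplicationError(ValueError):
    """Fewer than two replicate tanks in a group; the test is undefined."""


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    endpoint_name: str
    F: float
    df_num: int
    df_den: int
    p_value: float
    design: str  # "replicate_level" or "nested_individual"


def anova_replicate_level(
    groups: dict[str, np.ndarray], endpoint_name: str = ""
) -> AnovaResult:
    """One-way ANOVA on tank values, one array of tank values per diet."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise InsufficientReplicationError("need >= 2 diet groups")
    for diet, a in zip(groups, arrays):
        if a.size < 2:
            raise InsufficientReplicationError(
                f"diet {diet!r} has {a.size} tank(s); need >= 2"
            )
    F, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    if not np.isfinite(F):  # identical groups: zero variance everywhere
        F, p = 0.0, 1.0
    return AnovaResult(endpoint_name, float(F), k - 1, n - k, float(p),
                       "replicate_level")


def anova_nested(
    values,
    diet_labels,
    tank_labels,
    endpoint_name: str = "",
) -> AnovaResult:
    """Mixed one-way ANOVA: diet fixed, tank random and nested in diet.

    Tests the diet effect against the between-tank mean square,
    F = MS_diet / MS_tank(diet), with (a−1, T−a) degrees of freedom for a
    diets and T tanks.  For balanced data this is algebraically identical to
    a one-way ANOVA on tank means; testing fish-level values directly against
    the residual would be anticonservative because fish within a tank are
    correlated.
    """
    y = np.asarray(values, dtype=float)
    diet = np.asarray(diet_labels)
    tank = np.asarray(tank_labels)
    if not (y.shape == diet.shape == tank.shape):
        raise ValueError("values, diet_labels and tank_labels must align")

    tank_keys, tank_idx = np.unique(tank, return_inverse=True)
    tank_n = np.bincount(tank_idx)
    tank_sum = np.bincount(tank_idx, weights=y)
    tank_mean = tank_sum / tank_n
    # diet of each tank (a tank belongs to exactly one diet)
    tank_diet = np.empty(tank_keys.size, dtype=diet.dtype)
    tank_diet[tank_idx] = diet
    diet_keys, diet_of_tank = np.unique(tank_diet, return_inverse=True)
    a = diet_keys.size
    T = tank_keys.size
    if a < 2:
        raise InsufficientReplicationError("need >= 2 diet groups")
    tanks_per_diet = np.bincount(diet_of_tank)
    if tanks_per_diet.min() < 2:
        bad = diet_keys[tanks_per_diet < 2]
        raise InsufficientReplicationError(
            f"diet group(s) {bad.tolist()} have a single tank"
        )

    diet_n = np.bincount(diet_of_tank, weights=tank_n)
    diet_mean = np.bincount(diet_of_tank, weights=tank_sum) / diet_n
    grand_mean = y.mean()

    ss_diet = float(np.sum(diet_n * (diet_mean - grand_mean) ** 2))
    ss_tank = float(np.sum(tank_n * (tank_mean - diet_mean[diet_of_tank]) ** 2))
    df_num, df_den = a - 1, T - a
    ms_diet = ss_diet / df_num
    ms_tank = ss_tank / df_den
    if ms_tank == 0.0:
        F, p = (0.0, 1.0) if ms_diet == 0.0 else (np.inf, 0.0)
    else:
        F = ms_diet / ms_tank
        p = float(stats.f.sf(F, df_num, df_den))
    return AnovaResult(endpoint_name, float(F), df_num, df_den, p,
                       "nested_individual")


# --------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# --------------------------------------------------------------------------

def _log_chi_scaled_pdf(u: np.ndarray, nu: float) -> np.ndarray:
    # density of S/sigma where S^2 ~ sigma^2 chi2_nu / nu
    return (
        np.log(2.0)
        + 0.5 * nu * np.log(nu / 2.0)
        - special.gammaln(nu / 2.0)
        + (nu - 1.0) * np.log(u)
        - nu * u * u / 2.0
    )


_HERMITE_NODES, _HERMITE_WEIGHTS = np.polynomial.hermite.hermgauss(80)


def dunnett_max_abs_t_cdf(t: float, lambdas: np.ndarray, df: float) -> float:
    """P(max_i |T_i| < t) for many-to-one t statistics sharing one control.

    The contrasts have the product correlation structure
    corr(T_i, T_j) = λ_i λ_j with λ_i = sqrt(n_i/(n_i + n_0)), which makes
    the joint probability a double integral: a Gauss–Hermite quadrature over
    the shared control deviate and an adaptive quadrature over the pooled
    scale estimate (chi distribution with ``df`` degrees of freedom).
    Deterministic and accurate to well below 1e-8.
    """
    if t <= 0:
        return 0.0
    lam = np.asarray(lambdas, dtype=float)
    s = np.sqrt(1.0 - lam * lam)
    z = np.sqrt(2.0) * _HERMITE_NODES  # z ~ N(0,1) via Hermite transform
    w = _HERMITE_WEIGHTS / np.sqrt(np.pi)

    def inner(u: float) -> float:
        tu = t * u
        upper = (tu - lam[:, None] * z[None, :]) / s[:, None]
        lower = (-tu - lam[:, None] * z[None, :]) / s[:, None]
        prod = np.prod(
            special.ndtr(upper) - special.ndtr(lower), axis=0
        )
        return float(np.sum(w * prod))

    def integrand(u: float) -> float:
        return np.exp(_log_chi_scaled_pdf(np.asarray(u), df)) * inner(u)

    # the chi_nu/sqrt(nu) density concentrates near 1; integrate the two
    # sides of the mode separately, the upper tail out to where the density
    # is negligible for any df >= 1
    upper = 1.0 + 40.0 / np.sqrt(max(df, 1.0))
    v1, _ = integrate.quad(integrand, 0.0, 1.0, limit=200,
                           epsabs=1e-11, epsrel=1e-11)
    v2, _ = integrate.quad(integrand, 1.0, upper, limit=200,
                           epsabs=1e-11, epsrel=1e-11)
    return min(max(v1 + v2, 0.0), 1.0)


def dunnett_critical_value(
    lambdas: np.ndarray, df: float, alpha: float = ALPHA
) -> float:
    """Two-sided critical value c with P(max_i |T_i| >= c) = alpha."""
    f = lambda c: dunnett_max_abs_t_cdf(c, lambdas, df) - (1.0 - alpha)
    return float(optimize.brentq(f, 1e-6, 50.0, xtol=1e-10))


@dataclass(frozen=True)
class DunnettComparison:
    diet_id: str
    mean_diff: float
    t: float
    p_unadjusted: float
    p_adjusted: float


@dataclass(frozen=True)
class DunnettResult:
    endpoint_name: str
    control_id: str
    n_comparisons: int
    df: int
    comparisons: tuple[DunnettComparison, ...]

    def p_adjusted(self) -> dict[str, float]:
        return {c.diet_id: c.p_adjusted for c in self.comparisons}


def dunnett_vs_control(
    groups: dict[str, np.ndarray],
    control: str,
    endpoint_name: str = "",
) -> DunnettResult:
    """Dunnett's many-to-one test of every diet against the control diet.

    Pools the within-group variance across all groups (classical
    homoscedastic Dunnett; a Levene pre-check logs a warning when group
    variances look unequal, but no Welch switch is made).  Two-sided
    adjusted p-values come from the joint maximum-modulus distribution of
    the correlated t statistics via :func:`dunnett_max_abs_t_cdf`.
    """
    if control not in groups:
        raise KeyError(f"control diet {control!r} not among groups")
    test_ids = [g for g in groups if g != control]
    if not test_ids:
        raise InsufficientReplicationError("no non-control diets to test")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, a in arrays.items():
        if a.size < 2:
            raise InsufficientReplicationError(
                f"group {g!r} has {a.size} value(s); need >= 2"
            )

    try:
        _, p_lev = stats.levene(*arrays.values())
        if p_lev < ALPHA:
            log.warning(
                "Levene pre-check p=%.3g: group variances look unequal; "
                "classical pooled-variance Dunnett is still applied", p_lev,
            )
    except Exception:  # pragma: no cover - degenerate inputs
        pass

    y0 = arrays[control]
    n0 = y0.size
    N = sum(a.size for a in arrays.values())
    k = len(test_ids)
    df = N - (k + 1)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    s2 = ss_within / df
    lambdas = np.array(
        [np.sqrt(arrays[g].size / (arrays[g].size + n0)) for g in test_ids]
    )

    comparisons = []
    for i, g in enumerate(test_ids):
        yi = arrays[g]
        diff = yi.mean() - y0.mean()
        se = np.sqrt(s2 * (1.0 / yi.size + 1.0 / n0))
        t = diff / se if se > 0 else 0.0
        p_un = 2.0 * stats.t.sf(abs(t), df) if se > 0 else 1.0
        p_adj = 1.0 - dunnett_max_abs_t_cdf(abs(t), lambdas, df)
        comparisons.append(
            DunnettComparison(g, float(diff), float(t), float(p_un),
                              float(min(max(p_adj, 0.0), 1.0)))
        )
    return DunnettResult(endpoint_name, control, k, df, tuple(comparisons))


# --------------------------------------------------------------------------
# correlation and t-test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def dose_correlation(substitution_pct, values) -> CorrelationResult:
    """Pearson correlation between maize substitution level and an endpoint."""
    x = np.asarray(substitution_pct, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float


def ccd_comparison(group_a, group_b) -> TTestResult:
    """Unpaired pooled-variance t-test (0 % diet vs commercial control)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicationError("both groups need >= 2 tanks")
    res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):  # identical constant groups
        t, p = 0.0, 1.0
    return TTestResult(t, a.size + b.size - 2, p, float(a.mean() - b.mean()))
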
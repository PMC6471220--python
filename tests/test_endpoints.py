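"""Endpoint computations: allometry, RCF, AGR, somatic indices, energetics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmtrial import (
    build_endpoint_table,
    compute_agr,
    compute_cv,
    compute_gross_energy,
    compute_nutrient_uptake,
    compute_rcf,
    compute_somatic_index,
    fit_length_weight,
    load_range_finding_diets,
    load_reference_variety_diets,
)
from gmtrial.core_model import FecalSample, FeedRation, PooledOrganSample
from gmtrial.endpoints import (
    DegenerateFitError,
    InsufficientDataError,
    diet_composition_report,
)


def _fish_frame(L, W, day=0):
    return pd.DataFrame({
        "fish_id": [f"f{i}" for i in range(len(L))],
        "tank_id": "t1", "day": day,
        "sex": ["male", "female"] * (len(L) // 2) + ["male"] * (len(L) % 2),
        "weight_g": W, "fork_length_mm": L,
    })


class TestLengthWeightFit:
    def test_noiseless_power_law_recovered_exactly(self):
        L = np.linspace(25, 45, 50)
        W = 2.0e-5 * L**3.0
        m = fit_length_weight(_fish_frame(L, W))
        assert m.a == pytest.approx(2.0e-5, rel=1e-12)
        assert m.b == pytest.approx(3.0, abs=1e-12)
        assert m.n_fish == 50

    def test_noisy_fit_matches_normal_equations_oracle(self, rng):
        L = rng.uniform(25, 45, 200)
        W = 1.2e-5 * L**3.1 * np.exp(rng.normal(0, 0.1, 200))
        m = fit_length_weight(_fish_frame(L, W))
        # independent closed-form least squares on the log-log design
        X = np.column_stack([np.ones(200), np.log(L)])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(W))
        assert m.b == pytest.approx(beta[1], abs=1e-10)
        assert np.log(m.a) == pytest.approx(beta[0], abs=1e-10)

    def test_too_few_fish_rejected(self):
        L = np.linspace(30, 40, 9)
        with pytest.raises(InsufficientDataError):
            fit_length_weight(_fish_frame(L, 1e-5 * L**3))

    def test_constant_length_is_degenerate(self):
        L = np.full(20, 30.0)
        with pytest.raises(DegenerateFitError):
            fit_length_weight(_fish_frame(L, np.linspace(0.3, 0.5, 20)))


class TestRCF:
    def test_on_curve_fish_has_rcf_one(self):
        L = np.linspace(25, 45, 50)
        m = fit_length_weight(_fish_frame(L, 2e-5 * L**3))
        assert compute_rcf(2e-5 * 33.0**3, 33.0, m) == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        from gmtrial.endpoints import LengthWeightModel
        m = LengthWeightModel(a=2.0e-5, b=3.0, n_fish=50, fit_day=0)
        assert compute_rcf(0.648, 30.0, m) == pytest.approx(1.2, abs=1e-12)

    def test_fit_population_geometric_mean_is_one(self, rng):
        # log-log least squares: log-residuals sum to zero
        L = rng.uniform(25, 45, 120)
        W = 1.1e-5 * L**3.05 * np.exp(rng.normal(0, 0.13, 120))
        fish = _fish_frame(L, W)
        m = fit_length_weight(fish)
        rcf = compute_rcf(fish["weight_g"], fish["fork_length_mm"], m)
        assert np.exp(np.mean(np.log(rcf))) == pytest.approx(1.0, abs=1e-10)
        # at study-like noise the arithmetic mean prints as 1.00
        assert round(float(np.mean(rcf)), 2) == pytest.approx(1.0, abs=0.011)

    def test_rescaling_weight_and_coefficient_cancels(self, rng):
        from gmtrial.endpoints import LengthWeightModel
        m = LengthWeightModel(a=1.5e-5, b=3.0, n_fish=20, fit_day=0)
        m2 = LengthWeightModel(a=3.0e-5, b=3.0, n_fish=20, fit_day=0)
        W, L = 0.5, 33.0
        assert compute_rcf(2 * W, L, m2) == pytest.approx(compute_rcf(W, L, m))


class TestAGRAndSomaticIndex:
    def test_no_growth_gives_zero(self):
        assert compute_agr([30.0, 31.0], [30.0, 31.0], 28.0) == 0.0

    def test_forced_arithmetic(self):
        assert compute_agr([30.0], [33.0], 28.0) == pytest.approx(3.0 / 28.0)

    def test_non_positive_time_rejected(self):
        with pytest.raises(ValueError):
            compute_agr([30.0], [33.0], 0.0)

    @pytest.mark.parametrize("organ_w,body_w,expected", [
        (0.0, 15.0, 0.0),
        (0.15, 15.0, 1.0),
    ])
    def test_somatic_index_percent(self, organ_w, body_w, expected):
        s = PooledOrganSample("t1", "male", "liver", 10, organ_w, body_w)
        assert compute_somatic_index(s) == pytest.approx(expected)

    def test_somatic_index_scale_invariant(self):
        s1 = PooledOrganSample("t1", "male", "liver", 10, 0.2, 16.0)
        s2 = PooledOrganSample("t1", "male", "liver", 10, 0.4, 32.0)
        assert compute_somatic_index(s1) == compute_somatic_index(s2)


class TestDietEnergetics:
    def test_printed_gross_energy_cells(self):
        ccd = {"carbohydrates": 46.4, "proteins": 33.4, "lipids": 3.7}
        assert round(compute_gross_energy(ccd), 1) == 17.6
        mv9 = {"carbohydrates": 61.6, "proteins": 28.5, "lipids": 6.6}
        assert round(compute_gross_energy(mv9), 1) == 20.2
        zero = {"carbohydrates": 0.0, "proteins": 0.0, "lipids": 0.0}
        assert compute_gross_energy(zero) == 0.0

    @given(st.floats(0.01, 1.5), st.floats(1, 60), st.floats(1, 40),
           st.floats(0.5, 10))
    @settings(max_examples=50, deadline=None)
    def test_gross_energy_linear_in_composition(self, alpha, c, p, l):
        x = {"carbohydrates": c, "proteins": p, "lipids": l}
        ax = {k: alpha * v for k, v in x.items()}
        assert compute_gross_energy(ax) == pytest.approx(
            alpha * compute_gross_energy(x), rel=1e-12)

    def test_printed_cv_cells(self):
        carbs = [32.1, 34.7, 31.3, 31.5, 29.5, 27.5]
        assert round(compute_cv(carbs), 1) == 7.8
        lipids = [5.9, 2.9, 4.2, 4.7, 4.8, 5.8, 6.1, 5.1, 6.6, 4.2]
        assert round(compute_cv(lipids), 1) == 22.0
        assert compute_cv([3.0, 3.0, 3.0]) == 0.0

    @given(st.floats(0.1, 100))
    @settings(max_examples=30, deadline=None)
    def test_cv_scale_invariant(self, c):
        x = [3.1, 2.8, 3.5, 3.0]
        assert compute_cv([c * v for v in x]) == pytest.approx(
            compute_cv(x), rel=1e-9)

    def test_cv_error_cases(self):
        with pytest.raises(InsufficientDataError):
            compute_cv([1.0])
        with pytest.raises(ValueError):
            compute_cv([-1.0, 1.0])

    def test_composition_reports_mirror_published_tables(self):
        t1 = diet_composition_report(load_range_finding_diets())
        assert t1.loc["gross_energy_kj_g", "CCD"] == 17.6
        assert t1.loc["gross_energy_kj_g", "sub0"] == 14.9
        assert t1.loc["carbohydrates", "CV_pct"] == 7.8
        t2 = diet_composition_report(load_reference_variety_diets())
        assert t2.loc["gross_energy_kj_g", "MV9"] == 20.2
        assert t2.loc["lipids", "CV_pct"] == 22.0


class TestNutrientUptake:
    def _pair(self, feed, fecal):
        r = FeedRation("t1", {"carbohydrate": feed})
        f = FecalSample("t1", {"carbohydrate": fecal})
        return r, f

    @pytest.mark.parametrize("feed,fecal,expected", [
        (2000.0, 0.0, 100.0),
        (2000.0, 300.0, 85.0),
        (2000.0, 2000.0, 0.0),
    ])
    def test_uptake_fraction(self, feed, fecal, expected):
        r, f = self._pair(feed, fecal)
        out = compute_nutrient_uptake(r, f)
        assert out["carbohydrate"]["uptake_pct"] == pytest.approx(expected)

    def test_zero_feed_with_fecal_mass_rejected(self):
        r, f = self._pair(0.0, 10.0)
        with pytest.raises(ValueError):
            compute_nutrient_uptake(r, f)

    def test_uptake_antitone_in_fecal_mass(self):
        feed = 1500.0
        uptakes = [
            compute_nutrient_uptake(*self._pair(feed, fecal))["carbohydrate"]["uptake_pct"]
            for fecal in (0.0, 100.0, 500.0, 1500.0, 1800.0)
        ]
        assert all(a > b for a, b in zip(uptakes, uptakes[1:]))
        assert uptakes[-1] < 0  # flagged, not clipped


class TestEndpointTableAssembly:
    def test_structural_completeness(self, endpoint_table, range_finding_trial):
        frame = endpoint_table.frame
        for endpoint in ("AGR", "uptake_carbohydrate"):
            tanks = frame[frame["endpoint_name"] == endpoint]["tank_id"]
            assert tanks.nunique() == range_finding_trial.n_tanks
        hsi = frame[frame["endpoint_name"] == "HSI"]
        assert set(hsi["sex_stratum"]) == {"male", "female"}
        assert hsi.groupby("sex_stratum")["tank_id"].nunique().min() == 21

    def test_trial_without_feces_omits_uptake(self, range_finding_trial, lw_model):
        from dataclasses import replace
        trial = replace(range_finding_trial,
                        feces=range_finding_trial.feces.iloc[0:0])
        table = build_endpoint_table(trial, lw_model)
        assert not any(e.startswith("uptake") for e in table.endpoints())

    def test_known_organ_values_reproduced_exactly(self, range_finding_trial,
                                                   lw_model):
        table = build_endpoint_table(range_finding_trial, lw_model)
        organs = range_finding_trial.organs
        row = organs[(organs["organ"] == "liver")].iloc[0]
        expected = 100.0 * row["organ_weight_g"] / row["total_body_weight_g"]
        got = table.frame[
            (table.frame["endpoint_name"] == "HSI")
            & (table.frame["tank_id"] == row["tank_id"])
            & (table.frame["sex_stratum"] == row["sex"])
        ]["value"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-12)
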
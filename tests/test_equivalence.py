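"""Equivalence engine: variance components, ELs, scaled differences, verdicts."""

import numpy as np
import pandas as pd
import pytest

from gmtrial import (
    EquivalenceResult,
    SimulationConfig,
    classify_equivalence,
    compute_equivalence_limit,
    equivalence_report,
    fit_reference_variance_components,
    generate_equivalence_case_study,
    generate_reference_dataset,
    scaled_difference,
)
from gmtrial.equivalence import (
    DegenerateLimitError,
    InsufficientReferenceError,
    ReferenceVariationDataset,
    VarianceComponents,
)


def _vc(s2v=1.0, s2trial=0.0, n_varieties=10):
    return VarianceComponents(
        endpoint_name="e", grand_mean=0.0, sigma2_variety=s2v,
        sigma2_trial=s2trial, sigma2_tank=0.1, sigma2_residual=0.0,
        n_varieties=n_varieties, n_trials=1, n_tanks=30,
    )


def _ref_frame(rng, n_var=3, n_tank=2, s2v=1.0, s2t=0.25):
    rows = []
    for v in range(n_var):
        ve = rng.normal(0, np.sqrt(s2v))
        for t in range(n_tank):
            rows.append({
                "endpoint_name": "e", "variety_id": f"V{v}", "trial_id": "T1",
                "tank_id": f"V{v}_t{t}", "sex_stratum": "pooled",
                "value": 10.0 + ve + rng.normal(0, np.sqrt(s2t)),
            })
    return pd.DataFrame(rows)


class TestReferenceDataset:
    def test_too_few_varieties_rejected(self, rng):
        frame = _ref_frame(rng, n_var=2)
        with pytest.raises(InsufficientReferenceError):
            ReferenceVariationDataset(frame)

    def test_single_tank_variety_rejected(self, rng):
        frame = _ref_frame(rng, n_var=3)
        frame = frame[~((frame.variety_id == "V0") & (frame.tank_id == "V0_t1"))]
        with pytest.raises(InsufficientReferenceError):
            ReferenceVariationDataset(frame)


class TestVarianceComponents:
    def test_reml_equals_expected_mean_squares_when_balanced(self, rng):
        # balanced one-way random model: REML coincides with the
        # method-of-moments (expected-mean-squares) estimator
        frame = _ref_frame(rng, n_var=4, n_tank=2, s2v=4.0)
        vc = fit_reference_variance_components(frame, "e")
        tank_means = frame.groupby("variety_id")["value"].mean()
        ms_between = 2 * tank_means.var(ddof=1)
        ms_within = frame.groupby("variety_id")["value"].var(ddof=1).mean()
        s2v_mom = (ms_between - ms_within) / 2
        if s2v_mom > 0:  # interior optimum: REML == ANOVA estimator
            assert vc.sigma2_variety == pytest.approx(s2v_mom, abs=1e-6)
            assert vc.sigma2_tank == pytest.approx(ms_within, abs=1e-6)
        else:  # boundary: variety truncates to 0, tanks absorb everything
            assert vc.sigma2_variety == pytest.approx(0.0, abs=1e-6)
            assert vc.sigma2_tank == pytest.approx(
                frame["value"].var(ddof=1), rel=1e-4)
        assert vc.sigma2_residual == 0.0
        assert vc.trial_confounded

    def test_zero_variance_data_gives_zero_components(self):
        frame = _ref_frame(np.random.default_rng(0), s2v=0.0, s2t=0.0)
        frame["value"] = 5.0
        vc = fit_reference_variance_components(frame, "e")
        assert vc.total_variance == 0.0

    def test_no_variety_effect_estimated_near_zero(self):
        # sigma_variety = 0 truth: the variety component should collapse
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            frame = _ref_frame(rng, n_var=8, n_tank=4, s2v=0.0, s2t=1.0)
            vc = fit_reference_variance_components(frame, "e")
            hits += vc.sigma2_variety < 0.3 * vc.sigma2_tank
        assert hits >= 6

    def test_fish_level_recovery_moderate_scale(self):
        # 25 varieties x 6 tanks x 5 fish; averaged over seeds the REML
        # estimates track the generating components
        from gmtrial import EndpointSpec
        ep = EndpointSpec(name="y", family="normal", level="fish", baseline=0.0,
                          sigma_variety=1.0, sigma_tank=0.5, sigma_fish=0.25)
        cfg = SimulationConfig(design="natural_variation", n_varieties=25,
                               n_tanks_per_diet=6, n_fish_per_tank=5,
                               endpoints=[ep])
        est = np.zeros(3)
        seeds = range(4)
        for s in seeds:
            ref = generate_reference_dataset(cfg, s)
            vc = fit_reference_variance_components(ref, "y")
            est += [vc.sigma2_variety, vc.sigma2_tank, vc.sigma2_residual]
        est /= len(list(seeds))
        assert est[0] == pytest.approx(1.0, rel=0.25)
        assert est[1] == pytest.approx(0.25, rel=0.20)
        assert est[2] == pytest.approx(0.0625, rel=0.15)


class TestEquivalenceLimit:
    def test_between_population_sd(self):
        assert compute_equivalence_limit(_vc(s2v=4.0)) == 2.0

    def test_multiplier_is_linear(self):
        el1 = compute_equivalence_limit(_vc(s2v=2.5), multiplier=1.0)
        el196 = compute_equivalence_limit(_vc(s2v=2.5), multiplier=1.96)
        assert el196 == pytest.approx(1.96 * el1, rel=1e-12)

    def test_zero_variation_degenerate(self):
        with pytest.raises(DegenerateLimitError):
            compute_equivalence_limit(_vc(s2v=0.0))

    def test_fixed_mode_is_sample_sd(self, rng):
        x = rng.normal(0, 0.3, 40)
        el = compute_equivalence_limit(_vc(), mode="fixed", reference_values=x)
        assert el == pytest.approx(np.std(x, ddof=1))

    def test_el_estimate_tracks_generating_sd(self):
        # between-variety SD 0.3 truth, tank-level reference data
        from gmtrial import EndpointSpec
        ep = EndpointSpec(name="y", family="normal", level="tank", baseline=1.0,
                          sigma_variety=0.3, sigma_tank=0.12)
        cfg = SimulationConfig(design="natural_variation", n_varieties=12,
                               n_tanks_per_diet=3, endpoints=[ep])
        els = []
        for s in range(25):
            ref = generate_reference_dataset(cfg, s)
            vc = fit_reference_variance_components(ref, "y")
            if vc.sigma2_variety > 0:
                els.append(compute_equivalence_limit(vc))
        assert np.mean(els) == pytest.approx(0.3, rel=0.15)


class TestScaledDifference:
    def test_identical_means_give_zero(self):
        res = scaled_difference([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], el_absolute=0.5)
        assert res.scaled_estimate == 0.0
        assert res.ci_low < 0 < res.ci_high

    def test_antisymmetric_under_group_swap(self, rng):
        a, b = rng.normal(0, 1, 3), rng.normal(0.7, 1, 3)
        ab = scaled_difference(a, b, 0.8)
        ba = scaled_difference(b, a, 0.8)
        assert ab.scaled_estimate == pytest.approx(-ba.scaled_estimate, abs=1e-12)
        assert ab.ci_low == pytest.approx(-ba.ci_high, abs=1e-12)
        assert ab.ci_high == pytest.approx(-ba.ci_low, abs=1e-12)

    def test_scale_equivariance(self, rng):
        a, b = rng.normal(5, 1, 3), rng.normal(5.5, 1, 3)
        r1 = classify_equivalence(scaled_difference(a, b, 0.6))
        c = 7.3
        r2 = classify_equivalence(scaled_difference(c * a, c * b, c * 0.6))
        assert r2.scaled_estimate == pytest.approx(r1.scaled_estimate, rel=1e-9)
        assert r2.ci_low == pytest.approx(r1.ci_low, rel=1e-9)
        assert r2.verdict == r1.verdict

    def test_ci_coverage_nominal(self, rng):
        # 3 tanks/group, known EL: t-interval coverage of the true scaled shift
        reps, hits = 800, 0
        true_shift = 0.7
        for _ in range(reps):
            a = rng.normal(true_shift, 0.5, 3)
            b = rng.normal(0.0, 0.5, 3)
            r = scaled_difference(a, b, el_absolute=1.0)
            hits += r.ci_low <= true_shift <= r.ci_high
        assert hits / reps == pytest.approx(0.95, abs=0.025)

    def test_unit_shift_estimated_unbiased(self, rng):
        el = 0.4
        ests = [
            scaled_difference(rng.normal(el, 0.2, 3), rng.normal(0, 0.2, 3),
                              el).scaled_estimate
            for _ in range(800)
        ]
        assert np.mean(ests) == pytest.approx(1.0, abs=0.05)

    def test_el_must_be_positive(self):
        with pytest.raises(ValueError):
            scaled_difference([1.0, 2.0], [1.0, 2.0], 0.0)


class TestClassification:
    @pytest.mark.parametrize("est,lo,hi,verdict", [
        (0.5, 0.2, 0.8, "proof_of_equivalence"),
        (0.5, 0.2, 1.3, "equivalence_more_likely_than_not"),
        (1.4, 0.9, 1.9, "equivalence_not_likely"),
        (1.4, 1.2, 1.9, "proof_of_non_equivalence"),
        (-1.4, -1.9, -1.2, "proof_of_non_equivalence"),
    ])
    def test_interval_rule(self, est, lo, hi, verdict):
        res = EquivalenceResult("e", "GM_vs_WT", est, lo, hi, 1.0)
        assert classify_equivalence(res).verdict == verdict

    def test_shrinking_ci_never_leaves_proof(self):
        # verdict lattice: at fixed estimate, verdict strength is monotone
        # in CI width
        order = {"proof_of_equivalence": 0,
                 "equivalence_more_likely_than_not": 1}
        est = 0.5
        widths = [0.1, 0.4, 0.8, 1.6, 3.0]
        ranks = [
            order[classify_equivalence(
                EquivalenceResult("e", "c", est, est - w, est + w, 1.0)).verdict]
            for w in widths
        ]
        assert ranks == sorted(ranks)

    def test_power_declines_with_true_shift(self, rng):
        # P(proof of equivalence) is non-increasing in |true shift|/EL
        shifts = [0.0, 0.5, 1.0, 1.5, 2.0]
        proof_rate = []
        for s in shifts:
            wins = 0
            for _ in range(400):
                a = rng.normal(s, 0.25, 3)
                b = rng.normal(0.0, 0.25, 3)
                r = classify_equivalence(scaled_difference(a, b, 1.0))
                wins += r.verdict == "proof_of_equivalence"
            proof_rate.append(wins / 400)
        assert all(x >= y - 0.03 for x, y in zip(proof_rate, proof_rate[1:]))


def _small_specs():
    from gmtrial import EndpointSpec
    return [
        EndpointSpec(name="length_larval", family="normal", level="tank",
                     baseline=3.9, sigma_variety=0.08, sigma_tank=0.032),
        EndpointSpec(name="liver_protein_content", family="lognormal",
                     level="tank", baseline=12.0, sigma_variety=0.18,
                     sigma_tank=0.072),
    ]


class TestEquivalenceReport:
    def test_null_case_mostly_inside_limits_with_broad_cis(self):
        # no injected effects: most cells land inside (-1,+1), yet at 3
        # tanks/group the CIs are broad relative to the EL range, so proof
        # of equivalence stays the minority outcome
        specs = _small_specs()
        inside = proof = total = 0
        for seed in range(30):
            ref = generate_reference_dataset(
                SimulationConfig(design="natural_variation", endpoints=specs),
                seed)
            case = generate_equivalence_case_study(
                SimulationConfig(design="equivalence_case_study",
                                 endpoints=specs), 1000 + seed)
            rep = equivalence_report(case, ref,
                                     endpoints=[s.name for s in specs])
            ok = rep[rep["error"] == ""]
            total += len(ok)
            inside += (ok["scaled_estimate"].abs() < 1).sum()
            proof += (ok["verdict"] == "proof_of_equivalence").sum()
        assert inside / total >= 0.95
        assert proof / total < 0.5

    def test_endpoint_missing_from_reference_reported_not_fatal(self):
        specs = _small_specs()
        ref = generate_reference_dataset(
            SimulationConfig(design="natural_variation", endpoints=specs[:1]), 3)
        case = generate_equivalence_case_study(
            SimulationConfig(design="equivalence_case_study", endpoints=specs), 4)
        rep = equivalence_report(case, ref, endpoints=[s.name for s in specs])
        by_ep = rep.groupby("endpoint_name")["error"].apply(lambda e: (e != "").any())
        assert not by_ep["length_larval"]
        assert by_ep["liver_protein_content"]
        ok = rep[rep["endpoint_name"] == "length_larval"]
        assert set(ok["contrast"]) == {"GM_vs_NS", "GM_vs_WT", "NS_vs_WT"}

    def test_transformation_process_shift_pattern(self):
        # shift shared by GM and NS: GM~NS equivalent-leaning, both far from WT
        specs = _small_specs()
        shifts = {s.name: {"GM": 1.5, "NS": 1.5} for s in specs}
        gm_ns, gm_wt = [], []
        for seed in range(10):
            ref = generate_reference_dataset(
                SimulationConfig(design="natural_variation", endpoints=specs),
                seed)
            case = generate_equivalence_case_study(
                SimulationConfig(design="equivalence_case_study",
                                 endpoints=specs, arm_shifts=shifts),
                2000 + seed)
            rep = equivalence_report(case, ref,
                                     endpoints=[s.name for s in specs])
            ok = rep[rep["error"] == ""]
            gm_ns += list(ok.loc[ok["contrast"] == "GM_vs_NS", "scaled_estimate"])
            gm_wt += list(ok.loc[ok["contrast"] == "GM_vs_WT", "scaled_estimate"])
        assert abs(np.mean(gm_ns)) < 0.4
        assert np.mean(gm_wt) > 1.0
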
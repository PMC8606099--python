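import dataclasses

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import skew

from mediprod import (
    DegenerateSummaryError,
    MediationRequest,
    SimulationScenario,
    SolverError,
    evaluate,
    generate_dataset,
    intercept_from_prevalence,
    prevalence_sweep,
    run_scenario,
    solve_gamma1_for_correlation,
    solve_linear_outcome_params,
    solve_logistic_outcome_params,
    solve_scenario,
    theta_from_params,
)
from mediprod.simulate import SolvedParams, _summarize_measure


class TestGamma1Solver:
    def test_continuous_printed_constant(self):
        g1 = solve_gamma1_for_correlation("continuous", 0.2)
        assert round(g1, 3) == 0.408

    def test_binary_printed_constant(self):
        g1 = solve_gamma1_for_correlation("binary", 0.2, baseline_prev=0.2)
        assert g1 == pytest.approx(0.903, abs=1e-3)

    def test_zero_target(self):
        assert solve_gamma1_for_correlation("continuous", 0.0) == 0.0
        assert solve_gamma1_for_correlation("binary", 0.0, baseline_prev=0.2) == 0.0

    def test_unattainable_binary_correlation(self):
        with pytest.raises(ValueError, match="feasible"):
            solve_gamma1_for_correlation("binary", 0.9, baseline_prev=0.5)

    def test_continuous_round_trip(self):
        # implied population correlation at the solved slope
        g1 = solve_gamma1_for_correlation("continuous", 0.35, exposure_prob=0.3)
        v = 0.3 * 0.7
        corr = g1 * np.sqrt(v) / np.sqrt(g1**2 * v + 1.0)
        assert corr == pytest.approx(0.35, abs=1e-12)

    def test_negative_target(self):
        g1 = solve_gamma1_for_correlation("binary", -0.2, baseline_prev=0.5)
        assert g1 < 0


class TestInterceptFromPrevalence:
    @pytest.mark.parametrize(
        "prev,expected",
        [(0.5, 0.0), (0.2, np.log(0.25)), (0.03, np.log(0.03 / 0.97))],
    )
    def test_values(self, prev, expected):
        assert intercept_from_prevalence(prev) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("prev", [0.0, 1.0, -0.1, 1.5])
    def test_boundary_rejected(self, prev):
        with pytest.raises(ValueError):
            intercept_from_prevalence(prev)


class TestLinearSolver:
    def test_case1_printed_formulas(self):
        b1, b2 = solve_linear_outcome_params(1, te=1.0, mp=0.5, gamma0=0.0, gamma1=0.408)
        assert b1 == pytest.approx(0.5)
        assert b2 == pytest.approx(0.5 / 0.408)

    def test_zero_mp(self):
        b1, b2 = solve_linear_outcome_params(2, te=0.7, mp=0.0, gamma0=-1.386, gamma1=0.9)
        assert (b1, b2) == (0.7, 0.0)

    def test_case2_round_trip(self):
        g0, g1 = np.log(0.25), 0.903
        b1, b2 = solve_linear_outcome_params(2, te=0.5, mp=0.2, gamma0=g0, gamma1=g1)
        theta = theta_from_params([0.0, b1, b2], [g0, g1])
        est = evaluate(theta, MediationRequest(case=2))
        assert est.mp == pytest.approx(0.2, abs=1e-12)
        assert est.te == pytest.approx(0.5, abs=1e-12)

    def test_zero_gamma1_with_nonzero_mp_errors(self):
        with pytest.raises(SolverError):
            solve_linear_outcome_params(1, te=1.0, mp=0.2, gamma0=0.0, gamma1=0.0)


class TestLogisticSolver:
    @pytest.mark.parametrize("case", [3, 4])
    def test_round_trip_residuals(self, case):
        te, mp = np.log(1.5), 0.2
        beta0 = intercept_from_prevalence(0.03)
        if case == 3:
            gamma = [0.0, solve_gamma1_for_correlation("continuous", 0.2)]
            sigma2 = 1.0
        else:
            gamma = [
                intercept_from_prevalence(0.2),
                solve_gamma1_for_correlation("binary", 0.2, baseline_prev=0.2),
            ]
            sigma2 = None
        b1, b2 = solve_logistic_outcome_params(case, te, mp, beta0, gamma, sigma2)
        theta = theta_from_params([beta0, b1, b2], gamma, sigma2=sigma2)
        est = evaluate(theta, MediationRequest(case=case, expression="exact"))
        assert est.nie == pytest.approx(mp * te, abs=1e-8)
        assert est.nde == pytest.approx((1 - mp) * te, abs=1e-8)

    def test_zero_mp_degenerate_system(self):
        b1, b2 = solve_logistic_outcome_params(3, np.log(1.5), 0.0, -3.476, [0.0, 0.408], 1.0)
        assert b2 == 0.0
        assert b1 == pytest.approx(np.log(1.5))

    def test_beta1_monotone_in_te(self):
        solved = [
            solve_logistic_outcome_params(4, te, 0.2, -3.476, [np.log(0.25), 0.903])
            for te in (np.log(1.2), np.log(1.5), np.log(2.0))
        ]
        b1s = [s[0] for s in solved]
        assert b1s[0] < b1s[1] < b1s[2]


class TestGenerateDataset:
    def test_case1_correlation_target(self):
        sc = SimulationScenario(case=1, n=200_000, te=0.5, mp=0.2, reps=1, seed=1)
        ds = generate_dataset(sc, solve_scenario(sc), np.random.default_rng(1))
        assert np.corrcoef(ds.x, ds.m)[0, 1] == pytest.approx(0.2, abs=0.005)

    def test_case2_correlation_target(self):
        sc = SimulationScenario(case=2, n=200_000, te=0.5, mp=0.2, reps=1, seed=1)
        ds = generate_dataset(sc, solve_scenario(sc), np.random.default_rng(2))
        assert np.corrcoef(ds.x, ds.m)[0, 1] == pytest.approx(0.2, abs=0.005)

    def test_case4_baseline_outcome_prevalence(self):
        sc = SimulationScenario(case=4, n=500_000, te=np.log(1.5), mp=0.2, reps=1, seed=1)
        ds = generate_dataset(sc, solve_scenario(sc), np.random.default_rng(3))
        sel = (ds.x == 0) & (ds.m == 0)
        assert np.mean(ds.y[sel]) == pytest.approx(0.03, abs=0.002)

    def test_heteroskedastic_variance_ratio(self):
        sc = SimulationScenario(
            case=3, n=400_000, te=np.log(1.5), mp=0.2, reps=1, seed=1,
            error_model="heteroskedastic", error_param=1.0,
        )
        ds = generate_dataset(sc, solve_scenario(sc), np.random.default_rng(4))
        ratio = np.var(ds.m[ds.x == 1]) / np.var(ds.m[ds.x == 0])
        assert ratio == pytest.approx(3.0, abs=0.1)

    def test_heteroskedastic_overall_variance_one(self):
        sc = SimulationScenario(
            case=3, n=400_000, te=np.log(1.5), mp=0.2, reps=1, seed=1,
            error_model="heteroskedastic", error_param=0.5,
        )
        params = solve_scenario(sc)
        ds = generate_dataset(sc, params, np.random.default_rng(5))
        resid = ds.m - (params.gamma0 + params.gamma1 * ds.x)
        assert np.var(resid) == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("s", [1.0, 2.0])
    def test_gamma_error_moments(self, s):
        sc = SimulationScenario(
            case=3, n=400_000, te=np.log(1.5), mp=0.2, reps=1, seed=1,
            error_model="gamma_skew", error_param=s,
        )
        params = solve_scenario(sc)
        ds = generate_dataset(sc, params, np.random.default_rng(6))
        resid = ds.m - (params.gamma0 + params.gamma1 * ds.x)
        assert np.mean(resid) == pytest.approx(0.0, abs=0.01)
        assert np.var(resid) == pytest.approx(1.0, abs=0.02)
        assert skew(resid) == pytest.approx(s, abs=0.1)

    def test_confounder_enters_all_three_models(self):
        sc = SimulationScenario(
            case=1, n=300_000, te=0.5, mp=0.2, reps=1, seed=1,
            confounder=(0.4, 0.8, 0.6, 0.5),
        )
        ds = generate_dataset(sc, solve_scenario(sc), np.random.default_rng(7))
        assert ds.w.shape == (sc.n, 1)
        c = ds.w[:, 0]
        # exposure prevalence rises with the confounder
        assert np.mean(ds.x[c == 1]) > np.mean(ds.x[c == 0]) + 0.1
        # mediator mean shifts with the confounder within exposure arm
        assert np.mean(ds.m[(c == 1) & (ds.x == 0)]) > np.mean(
            ds.m[(c == 0) & (ds.x == 0)]
        ) + 0.3

    def test_non_normal_errors_require_continuous_mediator(self):
        with pytest.raises(ValueError):
            SimulationScenario(
                case=4, n=100, te=0.5, mp=0.2, reps=1, seed=1,
                error_model="gamma_skew", error_param=1.0,
            )


class TestRunScenario:
    def test_smoke_all_fields(self):
        sc = SimulationScenario(case=1, n=150, te=0.5, mp=0.2, reps=100, seed=5)
        summary = run_scenario(sc)
        ms = summary.results["exact"]["nie"]
        assert np.isfinite(ms.median_pct_bias)
        assert 0.0 <= ms.cr_delta <= 100.0
        assert ms.variance_ratio > 0
        assert isinstance(ms.cr_delta_flag, bool)
        assert summary.n_failed + ms.n_used == sc.reps

    def test_deterministic_under_seed(self):
        sc = SimulationScenario(case=1, n=200, te=0.5, mp=0.2, reps=50, seed=11)
        a, b = run_scenario(sc), run_scenario(sc)
        assert a.results["exact"]["nie"] == b.results["exact"]["nie"]
        assert a.results["exact"]["mp"] == b.results["exact"]["mp"]

    def test_case3_variant_fan_out(self):
        sc = SimulationScenario(
            case=3, n=2000, te=np.log(2.0), mp=0.5, reps=20, seed=3,
            outcome_prev=0.1, variants=("exact", "approx", "probit"),
        )
        summary = run_scenario(sc)
        assert set(summary.results) == {"exact", "approx", "probit"}
        for variant in summary.results.values():
            assert set(variant) == {"nie", "mp"}

    def test_bootstrap_coverage_recorded(self):
        sc = SimulationScenario(
            case=1, n=150, te=1.0, mp=0.5, reps=15, seed=2, bootstrap_R=100
        )
        summary = run_scenario(sc)
        ms = summary.results["exact"]["nie"]
        assert ms.cr_boot is not None and 0.0 <= ms.cr_boot <= 100.0

    def test_true_theta_oracle_hits_zero_bias_and_vr_error(self):
        # replacing the estimates by the truth in every rep: median bias is 0
        # and the empirical variance collapses, which must be an error
        est = [0.1] * 50
        var = [0.01] * 50
        with pytest.raises(DegenerateSummaryError):
            _summarize_measure(est, var, truth=0.1, cover=[True] * 50, boot_cover=None)

    def test_result1_holds_within_scenario(self):
        from mediprod import fit_mediator_model, fit_outcome_model

        sc = SimulationScenario(case=2, n=300, te=0.5, mp=0.2, reps=300, seed=13)
        params = solve_scenario(sc)
        betas, gammas = [], []
        for rep in range(sc.reps):
            rng = np.random.default_rng(np.random.SeedSequence(sc.seed, spawn_key=(rep,)))
            ds = generate_dataset(sc, params, rng)
            betas.append(fit_outcome_model(ds).coefficients)
            gammas.append(fit_mediator_model(ds).coefficients)
        corr = np.corrcoef(np.asarray(betas).T, np.asarray(gammas).T)[:3, 3:]
        assert np.max(np.abs(corr)) < 4.0 / np.sqrt(sc.reps)


class TestPrevalenceSweep:
    def test_requires_binary_outcome_case(self):
        sc = SimulationScenario(case=1, n=100, te=0.5, mp=0.2, reps=10, seed=1)
        with pytest.raises(ValueError):
            prevalence_sweep(sc, [0.01, 0.5])

    def test_sweep_length_and_resolved_intercepts(self):
        sc = SimulationScenario(case=4, n=500, te=np.log(2.0), mp=0.5, reps=10, seed=1)
        out = prevalence_sweep(sc, [0.05, 0.2, 0.4])
        assert len(out) == 3
        b0s = [s.params.beta0 for s in out]
        assert b0s[0] < b0s[1] < b0s[2]
        for s in out:
            assert set(s.results) == {"exact", "approx"}

    def test_approximate_truth_divergence_grows_with_prevalence(self):
        te, mp = np.log(1.2), 0.5
        rels = []
        for prev in (0.01, 0.1, 0.3, 0.5):
            sc = SimulationScenario(
                case=4, n=100, te=te, mp=mp, reps=1, seed=1, outcome_prev=prev
            )
            p = solve_scenario(sc)
            theta = theta_from_params([p.beta0, p.beta1, p.beta2], [p.gamma0, p.gamma1])
            approx = evaluate(theta, MediationRequest(case=4, expression="approx"))
            rels.append(abs(approx.nie - mp * te) / (mp * te))
        assert rels[0] < 0.01
        assert rels == sorted(rels)


class TestScenarioValidation:
    def test_case_validation(self):
        with pytest.raises(ValueError):
            SimulationScenario(case=5, n=100, te=0.5, mp=0.2, reps=1, seed=1)

    def test_mp_range(self):
        with pytest.raises(ValueError):
            SimulationScenario(case=1, n=100, te=0.5, mp=1.2, reps=1, seed=1)

    def test_probit_variant_only_case3(self):
        with pytest.raises(ValueError):
            SimulationScenario(
                case=4, n=100, te=0.5, mp=0.2, reps=1, seed=1,
                variants=("exact", "probit"),
            )

    def test_default_variants_by_case(self):
        assert SimulationScenario(case=1, n=10, te=0.5, mp=0.2, reps=1, seed=1).variants == ("exact",)
        assert SimulationScenario(case=3, n=10, te=0.5, mp=0.2, reps=1, seed=1).variants == (
            "exact",
            "approx",
        )


def test_solved_params_reproduce_targets_every_case():
    for case in (1, 2, 3, 4):
        te = 0.5 if case in (1, 2) else np.log(1.5)
        sc = SimulationScenario(case=case, n=10, te=te, mp=0.2, reps=1, seed=1)
        p = solve_scenario(sc)
        theta = theta_from_params(
            [p.beta0, p.beta1, p.beta2], [p.gamma0, p.gamma1], sigma2=p.sigma2
        )
        est = evaluate(theta, MediationRequest(case=case, expression="exact"))
        assert est.nie == pytest.approx(sc.mp * sc.te, abs=1e-8)
        assert est.nde == pytest.approx((1 - sc.mp) * sc.te, abs=1e-8)
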
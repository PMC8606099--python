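"""Synthetic data generation and Monte-Carlo operating characteristics.

Generators follow the four-case design: X ~ Bernoulli(q); a continuous
mediator M | X ~ Normal(g0 + g1*X, 1) or a binary mediator from a logistic
model; a continuous outcome Y ~ Normal(b0 + b1*X + b2*M, 1) or a binary
outcome from a logistic model.  Coefficients are calibrated so that the
*exact* measures hit a target (TE, MP):

* g1 solves Corr(X, M) = target (closed form for a continuous mediator,
  root-find on the exposed-arm prevalence for a binary one);
* intercepts are set from baseline prevalences via the logit;
* (b1, b2) come from closed forms for continuous outcomes and from a 2-D
  root-find on the exact NIE/NDE expressions for binary outcomes.

Sensitivity generators: exposure-dependent mediator variance
sigma_x^2 = eta0 + eta1*X with eta0 chosen so E[sigma_x^2] = 1, and
standardized gamma errors with shape (2/s)^2 and scale s/2 (skewness s,
mean 0, variance 1).  An optional binary confounder can enter the exposure,
mediator and outcome models.

:func:`run_scenario` replicates generate/fit/estimate and reports the
standard metrics: median percent bias, 95% CI coverage rates (delta and
optionally bootstrap) with a binomial-band flag, and the variance ratio
(median estimated variance over the empirical variance of the estimates).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.optimize
from scipy.special import expit, logit

from .data import Dataset
from .errors import DegenerateSummaryError, MediationError, SolverError
from .fitting import ThetaEstimate, assemble_theta, fit_mediator_model, fit_outcome_model
from .measures import MediationRequest, evaluate
from .uncertainty import BootstrapError, Z95, delta_variances, percentile_bootstrap

__all__ = [
    "SimulationScenario",
    "SolvedParams",
    "MeasureSummary",
    "SimulationSummary",
    "solve_gamma1_for_correlation",
    "intercept_from_prevalence",
    "solve_linear_outcome_params",
    "solve_logistic_outcome_params",
    "solve_scenario",
    "theta_from_params",
    "generate_dataset",
    "run_scenario",
    "prevalence_sweep",
]

_ROOT_TOL = 1e-10


@dataclass
class SimulationScenario:
    """Generator targets and study settings for one replication study."""

    case: int
    n: int
    te: float
    mp: float
    reps: int
    seed: int
    exposure_prob: float = 0.5
    mediator_prev: float = 0.2
    outcome_prev: float = 0.03
    corr_xm: float = 0.2
    variants: tuple = None
    bootstrap_R: int = None
    error_model: str = "normal"
    error_param: float = 0.0
    confounder: tuple = None  # (prevalence, coef_exposure, coef_mediator, coef_outcome)

    def __post_init__(self):
        if self.case not in (1, 2, 3, 4):
            raise ValueError(f"case must be 1-4, got {self.case}")
        if not 0.0 <= self.mp < 1.0:
            raise ValueError("mp target must lie in [0, 1)")
        if self.error_model not in ("normal", "heteroskedastic", "gamma_skew"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        if self.error_model != "normal" and self.case not in (1, 3):
            raise ValueError("non-normal error models require a continuous mediator")
        if self.variants is None:
            self.variants = ("exact",) if self.case in (1, 2) else ("exact", "approx")
        self.variants = tuple(self.variants)
        for v in self.variants:
            MediationRequest(case=self.case, expression=v)  # validates the combo
        if self.confounder is not None and len(self.confounder) != 4:
            raise ValueError(
                "confounder must be (prevalence, coef_x, coef_m, coef_y)"
            )


@dataclass
class SolvedParams:
    beta0: float
    beta1: float
    beta2: float
    gamma0: float
    gamma1: float
    sigma2: float = None  # mediator error variance (continuous mediator only)


@dataclass
class MeasureSummary:
    median_pct_bias: float
    cr_delta: float
    variance_ratio: float
    cr_delta_flag: bool
    cr_boot: float = None
    cr_boot_flag: bool = None
    n_used: int = 0


@dataclass
class SimulationSummary:
    scenario: SimulationScenario
    params: SolvedParams
    truth_nie: float
    truth_mp: float
    n_failed: int
    unreliable: bool
    results: dict  # variant -> measure -> MeasureSummary


# ---------------------------------------------------------------------------
# coefficient calibration


def solve_gamma1_for_correlation(
    mediator_type: str,
    target_corr: float,
    baseline_prev: float = None,
    exposure_prob: float = 0.5,
) -> float:
    """Exposure slope of the mediator model hitting Corr(X, M) = target.

    Continuous: X ~ Bernoulli(q), M | X ~ N(g0 + g1*X, 1), closed form
    g1 = rho / sqrt(v (1 - rho^2)) with v = q(1-q).  Binary: root-find on the
    exposed-arm prevalence p1, then g1 = logit(p1) - logit(p0).
    """
    q = exposure_prob
    if not 0.0 < q < 1.0:
        raise ValueError("exposure_prob must be in (0, 1)")
    v = q * (1.0 - q)
    rho = float(target_corr)
    if rho == 0.0:
        return 0.0
    if mediator_type == "continuous":
        if abs(rho) >= 1.0:
            raise ValueError("correlation target must lie in (-1, 1)")
        return rho / np.sqrt(v * (1.0 - rho**2))
    if mediator_type != "binary":
        raise ValueError(f"unknown mediator type {mediator_type!r}")
    p0 = baseline_prev
    if p0 is None or not 0.0 < p0 < 1.0:
        raise ValueError("binary mediator requires a baseline prevalence in (0, 1)")

    def corr_at(p1):
        pbar = q * p1 + (1.0 - q) * p0
        return v * (p1 - p0) / np.sqrt(v * pbar * (1.0 - pbar))

    lo, hi = (p0, 1.0 - 1e-12) if rho > 0 else (1e-12, p0)
    max_corr = corr_at(hi if rho > 0 else lo)
    if (rho > 0 and rho >= max_corr) or (rho < 0 and rho <= max_corr):
        raise ValueError(
            f"correlation {rho} unattainable for baseline prevalence {p0}; "
            f"feasible range is ({corr_at(lo + 1e-12):.4f}, {corr_at(hi - 1e-12):.4f})"
        )
    p1 = scipy.optimize.brentq(lambda p: corr_at(p) - rho, lo + 1e-12, hi, xtol=1e-14)
    return float(logit(p1) - logit(p0))


def intercept_from_prevalence(prev: float) -> float:
    """logit of a baseline prevalence (errors at the 0/1 boundary)."""
    if not 0.0 < prev < 1.0:
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {prev}")
    return float(logit(prev))


def solve_linear_outcome_params(case, te, mp, gamma0, gamma1):
    """Closed-form (b1, b2) for continuous-outcome cases 1 and 2."""
    if case not in (1, 2):
        raise ValueError("closed-form solver applies to cases 1 and 2 only")
    beta1 = (1.0 - mp) * te
    if mp == 0.0:
        return beta1, 0.0
    if case == 1:
        if gamma1 == 0.0:
            raise SolverError("mp != 0 is impossible with gamma1 = 0 (no mediated path)")
        return beta1, mp * te / gamma1
    jump = expit(gamma0 + gamma1) - expit(gamma0)
    if jump == 0.0:
        raise SolverError("mp != 0 is impossible with a flat mediator model")
    return beta1, mp * te / jump


def theta_from_params(beta, gamma, sigma2=None) -> ThetaEstimate:
    """A ThetaEstimate wrapping known true parameters (zero covariance)."""
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    return ThetaEstimate(
        beta=beta,
        gamma=gamma,
        cov_beta=np.zeros((beta.size, beta.size)),
        cov_gamma=np.zeros((gamma.size, gamma.size)),
        sigma2=sigma2,
        var_sigma2=0.0 if sigma2 is not None else None,
    )


def solve_logistic_outcome_params(case, te, mp, beta0, gamma, sigma2=None):
    """(b1, b2) such that the exact case-3/4 measures hit (TE, MP).

    Solves NIE(b1, b2) = mp*te and NDE(b1, b2) = (1-mp)*te by a 2-D
    root-find started at the rare-outcome approximate solution; residuals at
    the returned root are below 1e-10.
    """
    if case not in (3, 4):
        raise ValueError("the 2-D solver applies to cases 3 and 4 only")
    gamma = np.asarray(gamma, dtype=float)
    req = MediationRequest(case=case, expression="exact")

    def measures_at(beta1, beta2):
        theta = theta_from_params([beta0, beta1, beta2], gamma, sigma2=sigma2)
        est = evaluate(theta, req)
        return est.nie, est.nde

    if mp == 0.0:
        # with b2 = 0 the exact NDE reduces to b1*(x - x*) = b1
        return float(te), 0.0

    if case == 3:
        b2_start = mp * te / gamma[1]
    else:
        p1, p0 = expit(gamma[0] + gamma[1]), expit(gamma[0])
        b2_start = mp * te / (p1 - p0)
    x0 = np.array([(1.0 - mp) * te, b2_start])

    def residuals(b):
        nie, nde = measures_at(b[0], b[1])
        return [nie - mp * te, nde - (1.0 - mp) * te]

    sol = scipy.optimize.root(residuals, x0, method="hybr", tol=1e-13)
    resid = np.max(np.abs(residuals(sol.x)))
    if resid > _ROOT_TOL:
        sol = scipy.optimize.root(residuals, sol.x, method="lm", tol=1e-14)
        resid = np.max(np.abs(residuals(sol.x)))
    if resid > _ROOT_TOL:
        raise SolverError(
            f"calibration root-find failed (max residual {resid:.3e}; "
            f"message: {sol.message})"
        )
    return float(sol.x[0]), float(sol.x[1])


def solve_scenario(scenario: SimulationScenario) -> SolvedParams:
    """All generator coefficients implied by a scenario's targets."""
    sc = scenario
    cont_med = sc.case in (1, 3)
    gamma1 = solve_gamma1_for_correlation(
        "continuous" if cont_med else "binary",
        sc.corr_xm,
        baseline_prev=None if cont_med else sc.mediator_prev,
        exposure_prob=sc.exposure_prob,
    )
    gamma0 = 0.0 if cont_med else intercept_from_prevalence(sc.mediator_prev)
    sigma2 = 1.0 if cont_med else None
    if sc.case in (1, 2):
        beta0 = 0.0
        beta1, beta2 = solve_linear_outcome_params(sc.case, sc.te, sc.mp, gamma0, gamma1)
    else:
        beta0 = intercept_from_prevalence(sc.outcome_prev)
        beta1, beta2 = solve_logistic_outcome_params(
            sc.case, sc.te, sc.mp, beta0, [gamma0, gamma1], sigma2=sigma2
        )
    return SolvedParams(beta0, beta1, beta2, gamma0, gamma1, sigma2)


# ---------------------------------------------------------------------------
# data generation


def _mediator_errors(scenario, x, rng):
    n = x.size
    if scenario.error_model == "normal":
        return rng.standard_normal(n)
    if scenario.error_model == "heteroskedastic":
        eta1 = scenario.error_param
        eta0 = 1.0 - eta1 * scenario.exposure_prob  # E[sigma_x^2] = 1
        if eta0 <= 0 or eta0 + eta1 <= 0:
            raise ValueError("heteroskedastic variance must stay positive")
        sd = np.sqrt(eta0 + eta1 * x)
        return sd * rng.standard_normal(n)
    s = scenario.error_param  # gamma_skew
    if s <= 0:
        raise ValueError("gamma_skew requires a positive skewness parameter")
    k, theta = (2.0 / s) ** 2, s / 2.0
    b = rng.gamma(shape=k, scale=theta, size=n)
    return (b - k * theta) / (np.sqrt(k) * theta)


def generate_dataset(
    scenario: SimulationScenario, params: SolvedParams, rng: np.random.Generator
) -> Dataset:
    """One synthetic dataset drawn from the scenario's data-generating process."""
    sc, p = scenario, params
    n = sc.n
    if sc.confounder is not None:
        c_prev, a_x, a_m, a_y = sc.confounder
        c = rng.binomial(1, c_prev, size=n).astype(float)
        px = expit(logit(sc.exposure_prob) + a_x * c)
    else:
        c, a_m, a_y = None, 0.0, 0.0
        px = sc.exposure_prob
    x = rng.binomial(1, px, size=n).astype(float)
    med_lin = p.gamma0 + p.gamma1 * x + (a_m * c if c is not None else 0.0)
    if sc.case in (1, 3):
        m = med_lin + _mediator_errors(sc, x, rng)
    else:
        m = rng.binomial(1, expit(med_lin), size=n).astype(float)
    out_lin = p.beta0 + p.beta1 * x + p.beta2 * m + (a_y * c if c is not None else 0.0)
    if sc.case in (1, 2):
        y = out_lin + rng.standard_normal(n)
    else:
        y = rng.binomial(1, expit(out_lin), size=n).astype(float)
    return Dataset(
        y=y,
        x=x,
        m=m,
        w=c[:, None] if c is not None else None,
        y_type="continuous" if sc.case in (1, 2) else "binary",
        m_type="continuous" if sc.case in (1, 3) else "binary",
        w_names=("c",) if c is not None else (),
    )


# ---------------------------------------------------------------------------
# replication studies


def _rep_rng(seed, rep):
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))


def _estimate_once(data, requests):
    """Fit both models once and evaluate every requested variant."""
    outcome_fit = fit_outcome_model(data)
    mediator_fit = fit_mediator_model(data)
    theta = assemble_theta(outcome_fit, mediator_fit)
    out = {}
    for variant, req in requests.items():
        deltas = delta_variances(
            {
                "nie": lambda th, r=req: evaluate(th, r).nie,
                "mp": lambda th, r=req: evaluate(th, r).mp,
            },
            theta,
        )
        out[variant] = deltas
    return theta, out


def run_scenario(scenario: SimulationScenario) -> SimulationSummary:
    """Replicate generate/fit/estimate and aggregate operating characteristics."""
    sc = scenario
    params = solve_scenario(sc)
    truth = {"nie": sc.mp * sc.te, "mp": sc.mp}
    requests = {
        v: MediationRequest(case=sc.case, expression=v) for v in sc.variants
    }
    store = {
        v: {k: {"est": [], "var": [], "cover": [], "boot_cover": []} for k in truth}
        for v in sc.variants
    }
    n_failed = 0
    for rep in range(sc.reps):
        rng = _rep_rng(sc.seed, rep)
        data = generate_dataset(sc, params, rng)
        try:
            _, per_variant = _estimate_once(data, requests)
        except MediationError:
            n_failed += 1
            continue
        boot = None
        if sc.bootstrap_R:
            boot = _bootstrap_measures(data, requests, sc, rep)
            if boot is None:
                n_failed += 1
                continue
        for v, deltas in per_variant.items():
            for k in truth:
                d = deltas[k]
                store[v][k]["est"].append(d.estimate)
                store[v][k]["var"].append(d.variance)
                store[v][k]["cover"].append(d.ci[0] <= truth[k] <= d.ci[1])
                if boot is not None:
                    lo, hi = boot[v][k].ci
                    store[v][k]["boot_cover"].append(lo <= truth[k] <= hi)
    results = {}
    for v in sc.variants:
        results[v] = {
            k: _summarize_measure(
                store[v][k]["est"],
                store[v][k]["var"],
                truth[k],
                store[v][k]["cover"],
                store[v][k]["boot_cover"] if sc.bootstrap_R else None,
            )
            for k in truth
        }
    return SimulationSummary(
        scenario=sc,
        params=params,
        truth_nie=truth["nie"],
        truth_mp=truth["mp"],
        n_failed=n_failed,
        unreliable=n_failed > 0.1 * sc.reps,
        results=results,
    )


def _bootstrap_measures(data, requests, scenario, rep):
    boot_seed = int(
        np.random.SeedSequence(scenario.seed, spawn_key=(rep, 0xB007)).generate_state(1)[0]
    )
    out = {}
    for v, req in requests.items():

        def estimator(sample, r=req):
            fo = fit_outcome_model(sample)
            fm = fit_mediator_model(sample)
            est = evaluate(assemble_theta(fo, fm), r)
            return {"nie": est.nie, "mp": est.mp}

        try:
            out[v] = percentile_bootstrap(
                data, estimator, R=scenario.bootstrap_R, seed=boot_seed
            )
        except BootstrapError:
            return None
    return out


def _summarize_measure(est, var, truth, cover, boot_cover):
    est = np.asarray(est, dtype=float)
    var = np.asarray(var, dtype=float)
    b = est.size
    if b == 0:
        raise DegenerateSummaryError("no successful replications to summarize")
    if truth == 0.0:
        raise DegenerateSummaryError("percent bias undefined for a zero truth")
    bias = float(np.median((est - truth) / truth) * 100.0)
    emp_var = float(np.var(est, ddof=1)) if b > 1 else 0.0
    if emp_var <= (1e-12 * max(1.0, float(np.max(np.abs(est))))) ** 2:
        raise DegenerateSummaryError(
            "zero empirical variance across replications; variance ratio undefined"
        )
    vr = float(np.median(var) / emp_var)
    cr = float(np.mean(cover) * 100.0)
    half_band = Z95 * np.sqrt(0.95 * 0.05 / b) * 100.0
    summary = MeasureSummary(
        median_pct_bias=bias,
        cr_delta=cr,
        variance_ratio=vr,
        cr_delta_flag=bool(abs(cr - 95.0) > half_band),
        n_used=b,
    )
    if boot_cover is not None:
        crb = float(np.mean(boot_cover) * 100.0)
        summary.cr_boot = crb
        summary.cr_boot_flag = bool(abs(crb - 95.0) > half_band)
    return summary


def prevalence_sweep(base_scenario: SimulationScenario, prevalences) -> list:
    """Re-solve and rerun a binary-outcome scenario across outcome prevalences."""
    if base_scenario.case not in (3, 4):
        raise ValueError("the prevalence sweep applies to cases 3 and 4")
    out = []
    for prev in prevalences:
        sc = dataclasses.replace(
            base_scenario, outcome_prev=prev, variants=("exact", "approx")
        )
        out.append(run_scenario(sc))
    return out
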
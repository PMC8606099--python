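"""Interval estimation: multivariate delta method and percentile bootstrap.

The delta-method variance of a scalar measure f(theta) is
grad(f)' Sigma_theta grad(f), with the gradient obtained by central finite
differences (per-coordinate step 1e-6 * max(1, |theta_j|)) and Sigma_theta the
block-diagonal joint covariance from :func:`mediprod.fitting.assemble_theta`.
95% Wald intervals use the 1.96 normal multiplier.

The nonparametric pairs bootstrap resamples rows (Y, X, M, W jointly) with
replacement, refits everything per resample, and forms the interval from the
2.5th/97.5th percentiles (linear interpolation between order statistics).
Resamples whose refit fails (separation, non-convergence, degenerate columns)
are excluded and counted; more than 20% failures aborts the interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .errors import BootstrapError, MediationError
from .fitting import ThetaEstimate

__all__ = [
    "DeltaResult",
    "BootstrapResult",
    "delta_variance",
    "delta_variances",
    "wald_ci",
    "percentile_bootstrap",
]

Z95 = 1.96
FD_REL_STEP = 1e-6
MAX_FAILED_FRACTION = 0.2


@dataclass
class DeltaResult:
    estimate: float
    variance: float
    gradient: np.ndarray
    ci: tuple

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass
class BootstrapResult:
    replicates: np.ndarray  # successful replicates only
    ci: tuple
    n_failed: int
    seed: int


def wald_ci(estimate: float, variance: float) -> tuple:
    """(estimate - 1.96*sqrt(var), estimate + 1.96*sqrt(var))."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    half = Z95 * np.sqrt(variance)
    return (estimate - half, estimate + half)


def delta_variances(measures: dict, theta: ThetaEstimate) -> dict:
    """Delta-method results for several measures sharing one gradient sweep.

    ``measures`` maps names to callables ``f(theta) -> float``.
    """
    vec = theta.as_vector()
    sigma = theta.covariance()
    names = list(measures)
    center = np.array([float(measures[k](theta)) for k in names])
    if not np.all(np.isfinite(center)):
        raise MediationError("measure nonfinite at the parameter estimate")
    grads = np.empty((len(names), vec.size))
    for j in range(vec.size):
        h = FD_REL_STEP * max(1.0, abs(vec[j]))
        up, dn = vec.copy(), vec.copy()
        up[j] += h
        dn[j] -= h
        t_up, t_dn = theta.with_vector(up), theta.with_vector(dn)
        for i, k in enumerate(names):
            f_up, f_dn = float(measures[k](t_up)), float(measures[k](t_dn))
            if not (np.isfinite(f_up) and np.isfinite(f_dn)):
                raise MediationError(
                    f"measure {k!r} nonfinite at a perturbed parameter value"
                )
            grads[i, j] = (f_up - f_dn) / (2.0 * h)
    out = {}
    for i, k in enumerate(names):
        var = float(grads[i] @ sigma @ grads[i])
        if var < -1e-12:
            raise MediationError(
                f"delta-method variance of {k!r} is negative ({var:.3e})"
            )
        var = max(var, 0.0)
        out[k] = DeltaResult(
            estimate=float(center[i]),
            variance=var,
            gradient=grads[i].copy(),
            ci=wald_ci(float(center[i]), var),
        )
    return out


def delta_variance(measure, theta: ThetaEstimate) -> DeltaResult:
    """Delta-method variance and 95% Wald CI for one measure of theta."""
    return delta_variances({"_": measure}, theta)["_"]


def _degenerate(sample: Dataset) -> bool:
    # a resample with a constant exposure or mediator cannot identify the models
    return np.ptp(sample.x) == 0.0 or np.ptp(sample.m) == 0.0


def percentile_bootstrap(
    data: Dataset, estimator, R: int = 1000, seed: int = 0
) -> dict:
    """Percentile bootstrap CIs for every measure produced by ``estimator``.

    ``estimator(dataset) -> {name: value}`` must refit all model parameters on
    the resampled data.  Each resample draws its own RNG substream from
    ``(seed, resample index)``, so results are reproducible and order-independent.
    Returns ``{name: BootstrapResult}``.
    """
    if R < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    n = data.n
    values = None
    n_failed = 0
    for i in range(R):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        sample = data.take(rng.integers(0, n, size=n))
        if _degenerate(sample):
            n_failed += 1
            continue
        try:
            est = estimator(sample)
        except MediationError:
            n_failed += 1
            continue
        if values is None:
            values = {k: [] for k in est}
        for k, v in est.items():
            values[k].append(float(v))
    if n_failed > MAX_FAILED_FRACTION * R or values is None:
        raise BootstrapError(
            f"{n_failed}/{R} bootstrap resamples failed; interval unreliable"
        )
    out = {}
    for k, reps in values.items():
        reps = np.asarray(reps)
        lo, hi = np.percentile(reps, [2.5, 97.5], method="linear")
        out[k] = BootstrapResult(
            replicates=reps, ci=(float(lo), float(hi)), n_failed=n_failed, seed=seed
        )
    return out
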
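"""Regression fitting by estimating equations, with sandwich covariances.

The outcome model is ``g(E[Y|X,M,W]) = b0 + b1*X + b2*M + b3'W`` and the
mediator model is ``h(E[M|X,W]) = g0 + g1*X + g2'W``, with identity or logit
links and canonical working variances (constant for identity, mu(1-mu) for
logit).  Identity-link fits are the exact least-squares roots of the score
equation; logit-link fits are found by iteratively reweighted scoring.

The default covariance is the robust sandwich estimator; the model-based
(inverse-information) covariance is also computed and available on request.
For a continuous mediator the residual-variance estimating equation gives
``sigma2 = mean(r_i**2)`` (divisor n, the exact root) and
``var(sigma2) = mean((sigma2 - r_i**2)**2) / n``.

The two fits are asymptotically uncorrelated, so the joint parameter vector
theta = (beta, gamma[, sigma2]) has a strictly block-diagonal covariance; see
:func:`assemble_theta`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import expit

from .data import Dataset
from .errors import (
    ConvergenceError,
    DegenerateMediatorError,
    FitError,
    RankDeficiencyError,
    SeparationError,
)

__all__ = [
    "ModelFit",
    "ThetaEstimate",
    "fit_outcome_model",
    "fit_mediator_model",
    "sandwich_covariance",
    "assemble_theta",
]

MAX_ITER = 100
SCORE_TOL = 1e-10
SEPARATION_BOUND = 20.0


@dataclass
class ModelFit:
    """A fitted regression model with robust and model-based covariances."""

    coefficients: np.ndarray
    covariance: np.ndarray
    link: str
    converged: bool
    n_iterations: int
    covariance_type: str
    names: tuple
    n: int
    covariance_model_based: np.ndarray = None
    sigma2: float = None
    var_sigma2: float = None

    @property
    def n_params(self) -> int:
        return self.coefficients.size


@dataclass
class ThetaEstimate:
    """Stacked parameters (beta, gamma[, sigma2]) with block-diagonal covariance."""

    beta: np.ndarray
    gamma: np.ndarray
    cov_beta: np.ndarray
    cov_gamma: np.ndarray
    sigma2: float = None
    var_sigma2: float = None
    beta_names: tuple = ()
    gamma_names: tuple = ()

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)

    @property
    def has_sigma2(self) -> bool:
        return self.sigma2 is not None

    @property
    def n_params(self) -> int:
        return self.beta.size + self.gamma.size + (1 if self.has_sigma2 else 0)

    def as_vector(self) -> np.ndarray:
        parts = [self.beta, self.gamma]
        if self.has_sigma2:
            parts.append([self.sigma2])
        return np.concatenate(parts)

    def covariance(self) -> np.ndarray:
        """Joint covariance of theta; cross-blocks are exactly zero."""
        blocks = [self.cov_beta, self.cov_gamma]
        if self.has_sigma2:
            blocks.append(np.array([[self.var_sigma2]]))
        return scipy.linalg.block_diag(*blocks)

    def with_vector(self, vec) -> "ThetaEstimate":
        """A copy with the stacked parameter values replaced (same covariance)."""
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.n_params:
            raise ValueError("vector length does not match parameter count")
        nb, ng = self.beta.size, self.gamma.size
        return ThetaEstimate(
            beta=vec[:nb],
            gamma=vec[nb : nb + ng],
            cov_beta=self.cov_beta,
            cov_gamma=self.cov_gamma,
            sigma2=float(vec[-1]) if self.has_sigma2 else None,
            var_sigma2=self.var_sigma2,
            beta_names=self.beta_names,
            gamma_names=self.gamma_names,
        )


def sandwich_covariance(score_contributions, bread, names=None) -> np.ndarray:
    """Robust covariance A^{-1} B A^{-T} / n.

    Parameters
    ----------
    score_contributions : (n, q) array
        Per-subject score vectors evaluated at the estimate.
    bread : (q, q) array
        Average (negative) derivative of the per-subject score.
    names : sequence of str, optional
        Column names used in the singular-bread error message.
    """
    s = np.atleast_2d(np.asarray(score_contributions, dtype=float))
    a = np.atleast_2d(np.asarray(bread, dtype=float))
    n = s.shape[0]
    meat = s.T @ s / n
    try:
        a_inv = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        cols = _null_columns(a, names)
        raise RankDeficiencyError(
            f"singular bread matrix; collinear columns: {cols}", columns=cols
        ) from None
    return a_inv @ meat @ a_inv.T / n


def _null_columns(mat, names):
    q = mat.shape[0]
    names = tuple(names) if names else tuple(f"col{j}" for j in range(q))
    _, r, piv = scipy.linalg.qr(mat, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * q * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return tuple(names[j] for j in sorted(piv[rank:]))


def _check_design(design, names):
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        cols = _null_columns(design.T @ design, names)
        raise RankDeficiencyError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"collinear columns: {cols}",
            columns=cols,
        )
    if design.shape[0] < design.shape[1]:
        raise FitError("fewer observations than parameters")


def _fit_identity(design, response, names):
    _check_design(design, names)
    n = design.shape[0]
    xtx = design.T @ design
    coef = np.linalg.solve(xtx, design.T @ response)
    resid = response - design @ coef
    scores = design * resid[:, None]
    bread = xtx / n
    cov = sandwich_covariance(scores, bread, names)
    sigma2 = float(resid @ resid / n)
    cov_mb = sigma2 * np.linalg.inv(xtx)
    return coef, cov, cov_mb, resid, sigma2


def _fit_logit(design, response, names):
    _check_design(design, names)
    n, q = design.shape
    coef = np.zeros(q)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = design @ coef
        mu = expit(eta)
        score = design.T @ (response - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        wvar = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (design * wvar[:, None]).T @ design
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix during logistic fitting "
                "(likely separation or degenerate data)"
            ) from None
        coef = coef + step
        if np.max(np.abs(coef)) > SEPARATION_BOUND:
            raise SeparationError(
                f"coefficient magnitude exceeded {SEPARATION_BOUND} during "
                "logistic fitting; data are (quasi-)separated"
            )
    if not converged:
        raise ConvergenceError(
            f"logistic fit did not converge in {MAX_ITER} iterations "
            f"(max |score| = {np.max(np.abs(score)):.3e})"
        )
    mu = expit(design @ coef)
    wvar = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (design * wvar[:, None]).T @ design
    scores = design * (response - mu)[:, None]
    bread = info / n
    cov = sandwich_covariance(scores, bread, names)
    cov_mb = np.linalg.inv(info)
    return coef, cov, cov_mb, it


def fit_outcome_model(
    data: Dataset, link: str = None, covariates=None, covariance: str = "sandwich"
) -> ModelFit:
    """Fit ``g(E[Y|X,M,W]) = b0 + b1*X + b2*M + b3'W``.

    ``link`` defaults to identity for a continuous outcome and logit for a
    binary one; an explicit link must match the declared outcome type.
    """
    link = _resolve_link(link, data.y_type, "outcome")
    wsub, wnames = data.covariate_columns(covariates)
    design = np.column_stack([np.ones(data.n), data.x, data.m, wsub])
    names = ("intercept", "x", "m", *wnames)
    return _build_fit(design, data.y, link, names, covariance, data.n)


def fit_mediator_model(
    data: Dataset, link: str = None, covariates=None, covariance: str = "sandwich"
) -> ModelFit:
    """Fit ``h(E[M|X,W]) = g0 + g1*X + g2'W``.

    For the identity link also solves the residual-variance estimating
    equation: ``sigma2 = mean(r**2)`` with variance ``mean((sigma2 - r**2)**2)/n``.
    """
    link = _resolve_link(link, data.m_type, "mediator")
    wsub, wnames = data.covariate_columns(covariates)
    design = np.column_stack([np.ones(data.n), data.x, wsub])
    names = ("intercept", "x", *wnames)
    fit = _build_fit(design, data.m, link, names, covariance, data.n)
    if link == "identity":
        resid = data.m - design @ fit.coefficients
        sigma2 = float(resid @ resid / data.n)
        if sigma2 <= 1e-12 * max(1.0, float(np.mean(data.m**2))):
            raise DegenerateMediatorError(
                "mediator residual variance is zero; the mediator is an exact "
                "linear function of the predictors"
            )
        fit.sigma2 = sigma2
        fit.var_sigma2 = float(np.mean((sigma2 - resid**2) ** 2) / data.n)
    return fit


def _resolve_link(link, declared_type, which):
    canonical = "identity" if declared_type == "continuous" else "logit"
    if link is None:
        return canonical
    if link not in ("identity", "logit"):
        raise ValueError(f"unknown link {link!r}")
    if link != canonical:
        raise ValueError(
            f"{which} is declared {declared_type} which requires the "
            f"{canonical} link, got {link!r}"
        )
    return link


def _build_fit(design, response, link, names, covariance, n):
    if covariance not in ("sandwich", "model_based"):
        raise ValueError(f"unknown covariance type {covariance!r}")
    if link == "identity":
        coef, cov, cov_mb, _, _ = _fit_identity(design, response, names)
        it, converged = 1, True
    else:
        coef, cov, cov_mb, it = _fit_logit(design, response, names)
        converged = True
    return ModelFit(
        coefficients=coef,
        covariance=cov if covariance == "sandwich" else cov_mb,
        link=link,
        converged=converged,
        n_iterations=it,
        covariance_type=covariance,
        names=tuple(names),
        n=n,
        covariance_model_based=cov_mb,
    )


def assemble_theta(outcome_fit: ModelFit, mediator_fit: ModelFit) -> ThetaEstimate:
    """Stack the two fits into theta with block-diagonal covariance.

    sigma2 is carried exactly when the outcome is logistic and the mediator is
    continuous (the only configuration whose measures use it).
    """
    if not (outcome_fit.converged and mediator_fit.converged):
        raise FitError("cannot assemble theta from a non-converged fit")
    keep_sigma2 = outcome_fit.link == "logit" and mediator_fit.link == "identity"
    return ThetaEstimate(
        beta=outcome_fit.coefficients,
        gamma=mediator_fit.coefficients,
        cov_beta=outcome_fit.covariance,
        cov_gamma=mediator_fit.covariance,
        sigma2=mediator_fit.sigma2 if keep_sigma2 else None,
        var_sigma2=mediator_fit.var_sigma2 if keep_sigma2 else None,
        beta_names=outcome_fit.names,
        gamma_names=mediator_fit.names,
    )
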
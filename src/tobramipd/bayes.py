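"""Discrete Bayesian individual estimation over a nonparametric prior.

Given a course's dosing history, covariates and peak/trough concentrations,
the posterior over the prior's support points is computed by multiplying the
prior weight of each point with a Gaussian observation likelihood
(SD = c0 + c1·C, evaluated at the model-predicted concentration) and
normalizing with log-sum-exp stabilization.

Below-limit observations (< 0.2 mg/L) are substituted at half the limit
(0.1 mg/L) before fitting. When the standard fit is inadequate — posterior
mass piled on the prior boundary, or a poor fit to the observations — a
hybrid refit widens the parameter ranges and dilutes the prior with a
quasi-random auxiliary grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import qmc

from .pk import (
    PARAM_NAMES,
    CovariateSet,
    MicroParams,
    Regimen,
    SupportPoint,
    profile_matrix,
)
from .priors import DiscretePrior

__all__ = [
    "Observation",
    "AssayErrorModel",
    "Posterior",
    "FitMetrics",
    "FitReport",
    "DegenerateFitError",
    "UnfittableCourseError",
    "LLOQ_MG_L",
    "BLQ_SUBSTITUTE_MG_L",
    "assay_sd",
    "preprocess_blq",
    "log_likelihood",
    "posterior_weights",
    "hybrid_fit",
    "fit_is_inadequate",
    "point_estimates",
    "fit_metrics",
]

#: assay lower limit of quantification, mg/L
LLOQ_MG_L = 0.2
#: working value substituted for below-limit observations (half the LLOQ)
BLQ_SUBSTITUTE_MG_L = 0.1

# hybrid-fit policy constants (range expansion factor per bound, auxiliary
# grid size and total prior mass, trigger thresholds)
HYBRID_EXPANSION = 2.0
HYBRID_N_AUX = 500
HYBRID_AUX_MASS = 0.5
HYBRID_BOUNDARY_MASS_TRIGGER = 0.5
HYBRID_MAPE_TRIGGER = 20.0  # percent
# log-scale closeness to a bound counting as "on boundary"; 1% per edge keeps
# the prior's own boundary mass near 10% (1 - 0.98^5) so the 50% trigger
# detects genuine edge-piling rather than mere posterior diffuseness
_BOUNDARY_FRACTION = 0.01


class DegenerateFitError(RuntimeError):
    """All posterior weights underflowed to zero; the hybrid fit should run."""


class UnfittableCourseError(RuntimeError):
    """The course cannot be fit even after hybrid range expansion."""


@dataclass(frozen=True)
class Observation:
    """One measured concentration: time (h from course start), value (mg/L),
    BLQ flag and sampling role."""

    time: float
    concentration: float
    blq: bool = False
    role: str = "other"  # {"peak", "trough", "other"}

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be >= 0 h")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0 mg/L")
        if self.role not in ("peak", "trough", "other"):
            raise ValueError(f"unknown observation role {self.role!r}")


@dataclass(frozen=True)
class AssayErrorModel:
    """Linear assay-error polynomial: SD(C) = c0 + c1 * C (mg/L).

    Defaults: c0 = 0.1 mg/L (half the limit of quantification) and c1 = 0.04
    (the assay's 4% between-run CV bound). The clinical assay's exact error
    polynomial is configurable because it is site-specific.
    """

    c0: float = 0.1
    c1: float = 0.04

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.c1 < 0:
            raise ValueError("c0 and c1 must be >= 0")
        if self.c0 == 0 and self.c1 == 0:
            raise ValueError("c0 and c1 must not both be 0")


def assay_sd(concentration, model: AssayErrorModel):
    """Assay standard deviation at the (model-predicted) concentration."""
    return model.c0 + model.c1 * np.asarray(concentration, dtype=float)


def preprocess_blq(
    observations: Sequence[Observation],
    *,
    lloq: float = LLOQ_MG_L,
    substitute: float = BLQ_SUBSTITUTE_MG_L,
) -> list[Observation]:
    """Substitute observations strictly below the LLOQ at half the LLOQ.

    A value of exactly ``lloq`` is quantifiable and kept unchanged.
    """
    out = []
    for obs in observations:
        if obs.concentration < lloq:
            out.append(replace(obs, concentration=substitute, blq=True))
        else:
            out.append(obs)
    return out


def _predictions_matrix(
    theta: np.ndarray, cov: CovariateSet, regimen: Regimen, times: np.ndarray
) -> np.ndarray:
    """Model-predicted concentrations, shape (n_points, n_times), for
    population-scale parameter rows mapped through the covariate model."""
    clcr = cov.clcr
    v1 = theta[:, 0] * cov.body_weight
    ke = theta[:, 1] + theta[:, 2] * clcr
    return profile_matrix(v1, ke, theta[:, 3], theta[:, 4], regimen.events, times)


def _log_likelihoods(
    theta: np.ndarray,
    cov: CovariateSet,
    regimen: Regimen,
    observations: Sequence[Observation],
    err: AssayErrorModel,
) -> np.ndarray:
    times = np.array([o.time for o in observations], dtype=float)
    order = np.argsort(times, kind="stable")
    obs_sorted = np.array([observations[i].concentration for i in order], dtype=float)
    pred = _predictions_matrix(theta, cov, regimen, times[order])
    sd = assay_sd(pred, err)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = -0.5 * ((obs_sorted - pred) / sd) ** 2 - np.log(sd * math.sqrt(2 * math.pi))
    ll = np.where(np.isfinite(ll), ll, -np.inf)
    return ll.sum(axis=1)


def log_likelihood(
    point: SupportPoint,
    cov: CovariateSet,
    regimen: Regimen,
    observations: Sequence[Observation],
    err: AssayErrorModel,
) -> float:
    """Gaussian log-likelihood of one support point for one course.

    Predictions are evaluated at the *recorded* sampling times with the
    recorded infusion durations, not the nominal schedule. BLQ preprocessing
    must already have been applied. A non-finite prediction yields -inf
    (the point is excluded), never an exception.
    """
    if not observations:
        raise ValueError("at least one observation is required")
    return float(
        _log_likelihoods(point.as_array()[None, :], cov, regimen, observations, err)[0]
    )


@dataclass
class Posterior:
    """Posterior weights over a discrete support after seeing one course."""

    prior: DiscretePrior
    weights: np.ndarray
    log_evidence: float
    hybrid_used: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        total = self.weights.sum()
        if not math.isfinite(total) or total <= 0:
            raise ValueError("posterior weights must have positive finite mass")
        self.weights = self.weights / total

    @property
    def theta(self) -> np.ndarray:
        return self.prior.theta

    @property
    def points(self) -> list[SupportPoint]:
        return [
            SupportPoint(*row, weight=float(w))
            for row, w in zip(self.prior.theta, self.weights)
        ]

    def mean_theta(self) -> np.ndarray:
        """Posterior-weighted mean population-scale parameter vector."""
        return self.weights @ self.prior.theta


def posterior_weights(
    prior: DiscretePrior,
    cov: CovariateSet,
    regimen: Regimen,
    observations: Sequence[Observation],
    err: AssayErrorModel,
) -> Posterior:
    """Bayes update of the discrete prior against a course's observations.

    ``w_i ∝ prior_i · exp(logL_i)`` with log-sum-exp stabilization; with no
    observations the posterior equals the prior and the evidence is 0.
    Raises :class:`DegenerateFitError` when every point's likelihood
    underflows (all -inf), signaling that the hybrid fit should run.
    """
    if not observations:
        return Posterior(prior, prior.weights.copy(), log_evidence=0.0)
    ll = _log_likelihoods(prior.theta, cov, regimen, observations, err)
    m = np.max(ll)
    if not math.isfinite(m):
        raise DegenerateFitError(
            "all support points have vanishing likelihood; run hybrid_fit"
        )
    # shift the log-likelihoods (not the joint log-weights) so that adding a
    # constant to every logL leaves the weights bit-identical
    unnorm = prior.weights * np.exp(ll - m)
    total = unnorm.sum()
    if total <= 0:
        raise DegenerateFitError(
            "posterior mass underflowed to zero; run hybrid_fit"
        )
    return Posterior(prior, unnorm / total, log_evidence=float(m + math.log(total)))


def _boundary_mass(post: Posterior) -> float:
    """Posterior mass on points lying near any bound of the prior's box
    (within 5% of the dimension's log-range of either edge)."""
    lo = post.prior.bounds[:, 0]
    hi = post.prior.bounds[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lo, log_hi = np.log(lo), np.log(hi)
        span = np.where(log_hi > log_lo, log_hi - log_lo, 1.0)
        frac = (np.log(post.prior.theta) - log_lo) / span
    near = (frac <= _BOUNDARY_FRACTION) | (frac >= 1.0 - _BOUNDARY_FRACTION)
    return float(post.weights[near.any(axis=1)].sum())


def fit_is_inadequate(
    post: Posterior,
    cov: CovariateSet,
    regimen: Regimen,
    observations: Sequence[Observation],
) -> bool:
    """Hybrid-fit trigger: > 50% of posterior mass on boundary points, or
    median absolute percentage error of the point-estimate fit > 20%."""
    if _boundary_mass(post) > HYBRID_BOUNDARY_MASS_TRIGGER:
        return True
    est = point_estimates(post, cov, regimen, observations)
    metrics = fit_metrics(
        [o.concentration for o in observations], list(est.predictions)
    )
    return metrics.median_ape > HYBRID_MAPE_TRIGGER


def _expanded_prior(prior: DiscretePrior, seed: int) -> DiscretePrior:
    lo = prior.bounds[:, 0] / HYBRID_EXPANSION
    hi = prior.bounds[:, 1] * HYBRID_EXPANSION
    sampler = qmc.Sobol(d=len(PARAM_NAMES), scramble=True, rng=np.random.default_rng(seed))
    m = int(np.ceil(np.log2(HYBRID_N_AUX)))
    unit = sampler.random_base2(m)[:HYBRID_N_AUX]
    aux = np.exp(np.log(lo) + unit * (np.log(hi) - np.log(lo)))
    theta = np.vstack([prior.theta, aux])
    weights = np.concatenate(
        [
            prior.weights * (1.0 - HYBRID_AUX_MASS),
            np.full(HYBRID_N_AUX, HYBRID_AUX_MASS / HYBRID_N_AUX),
        ]
    )
    bounds = np.column_stack([lo, hi])
    return DiscretePrior(theta, weights, bounds, label=prior.label + " [hybrid-expanded]")


def hybrid_fit(
    prior: DiscretePrior,
    cov: CovariateSet,
    regimen: Regimen,
    observations: Sequence[Observation],
    err: AssayErrorModel,
    *,
    seed: int = 0,
) -> Posterior:
    """Refit with widened ranges and diluted prior information.

    Each dimension's bounds are widened by a factor of 2 at both ends, a
    quasi-random auxiliary grid of 500 points is appended carrying half the
    prior mass, and the Bayes update is re-run. Raises
    :class:`UnfittableCourseError` if the fit is still degenerate.
    """
    expanded = _expanded_prior(prior, seed)
    try:
        post = posterior_weights(expanded, cov, regimen, observations, err)
    except DegenerateFitError as exc:
        raise UnfittableCourseError(
            "course remains unfittable after hybrid range expansion "
            f"(n_obs={len(observations)}, clcr={cov.clcr:.1f} mL/min)"
        ) from exc
    post.hybrid_used = True
    return post


@dataclass(frozen=True)
class PointEstimates:
    """Posterior point estimates: population- and individual-scale parameters
    plus posterior-predictive concentrations at the observation times (in
    input order)."""

    theta: np.ndarray  # posterior-mean (vs, ki, ks, k12, k21)
    micro: MicroParams
    predictions: np.ndarray
    clearance: float  # ke * v1, L/h


def point_estimates(
    post: Posterior,
    cov: CovariateSet,
    regimen: Regimen,
    observations: Sequence[Observation],
) -> PointEstimates:
    """Posterior point estimates and predictive concentrations.

    Parameter estimates (and the derived clearance) are the weighted-mean
    population-scale parameters mapped through the covariate model.
    Predicted concentrations are those of the maximum-posterior-weight
    support point (the Bayesian individual fit): predicting from the mean
    parameters instead would systematically misstate the trough, which
    depends exponentially on the elimination constant.
    """
    theta = post.mean_theta()
    clcr = cov.clcr
    micro = MicroParams(
        v1=theta[0] * cov.body_weight,
        ke=theta[1] + theta[2] * clcr,
        k12=theta[3],
        k21=theta[4],
    )
    if observations:
        times = np.array([o.time for o in observations], dtype=float)
        order = np.argsort(times, kind="stable")
        map_idx = int(np.argmax(post.weights))
        pred_sorted = _predictions_matrix(
            post.theta[map_idx:map_idx + 1], cov, regimen, times[order]
        )[0]
        pred = np.empty_like(pred_sorted)
        pred[order] = pred_sorted
    else:
        pred = np.empty(0)
    return PointEstimates(
        theta=theta, micro=micro, predictions=pred, clearance=micro.clearance
    )


@dataclass(frozen=True)
class FitMetrics:
    """Predictive-performance summary.

    Sign convention: prediction error PE = predicted - observed, so a
    negative median PE means the model slightly underpredicts.
    """

    pe: np.ndarray
    ape: np.ndarray  # % ; excludes observations equal to 0
    median_pe: float
    iqr_pe: tuple[float, float]
    median_ape: float
    iqr_ape: tuple[float, float]
    r2: float
    n_excluded_zero: int = 0


def fit_metrics(observed: Sequence[float], predicted: Sequence[float]) -> FitMetrics:
    """Prediction error, absolute percentage error and R² of the
    observed-vs-predicted regression.

    Observations equal to zero are excluded from the percentage error with a
    warning; a constant predicted vector gets R² = 0 by convention.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    pe = pred - obs
    nonzero = obs != 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} observation(s) equal to 0 excluded from APE", stacklevel=2
        )
    ape = 100.0 * np.abs(pe[nonzero]) / obs[nonzero]
    if ape.size == 0:
        median_ape, iqr_ape = math.nan, (math.nan, math.nan)
    else:
        median_ape = float(np.median(ape))
        iqr_ape = (float(np.percentile(ape, 25)), float(np.percentile(ape, 75)))
    if obs.size >= 2 and np.ptp(pred) > 0 and np.ptp(obs) > 0:
        r = np.corrcoef(obs, pred)[0, 1]
        r2 = float(r * r)
    else:
        r2 = 0.0 if (obs.size >= 2) else 1.0 if np.allclose(obs, pred) else 0.0
    return FitMetrics(
        pe=pe,
        ape=ape,
        median_pe=float(np.median(pe)),
        iqr_pe=(float(np.percentile(pe, 25)), float(np.percentile(pe, 75))),
        median_ape=median_ape,
        iqr_ape=iqr_ape,
        r2=r2,
    )


@dataclass(frozen=True)
class FitReport:
    """Everything the TDM pipeline reports about one course's fit."""

    observations: tuple[Observation, ...]
    estimates: PointEstimates
    metrics: FitMetrics
    posterior: Posterior
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        est = self.estimates
        return {
            "n_observations": len(self.observations),
            "predicted": [float(p) for p in est.predictions],
            "observed": [o.concentration for o in self.observations],
            "prediction_error": [float(x) for x in self.metrics.pe],
            "median_pe_mg_L": self.metrics.median_pe,
            "median_ape_pct": self.metrics.median_ape,
            "r2": self.metrics.r2,
            "v1_L": est.micro.v1,
            "ke_per_h": est.micro.ke,
            "clearance_L_h": est.clearance,
            "hybrid_used": self.posterior.hybrid_used,
            "warnings": list(self.warnings),
        }
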
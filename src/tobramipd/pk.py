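"""Closed-form two-compartment IV-infusion kinetics with covariate-linked parameters.

The population model is parameterized on a body-size / renal-function scale:

* ``V1 = Vs * BW`` — central volume (L) scales linearly with body weight (kg),
* ``Ke = KI + KS * CLCR`` — elimination rate constant (1/h) is linear in
  creatinine clearance (mL/min), with a non-renal intercept ``KI``,

plus first-order intercompartmental constants ``k12``/``k21``. Concentrations
in the central compartment follow the classic bi-exponential solution with
hybrid constants alpha/beta, superposed over zero-order infusion events.

All times are in hours; each course's clock starts at the first infusion
start. Creatinine is stored in µmol/L and converted internally for the
Cockcroft–Gault estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CovariateSet",
    "SupportPoint",
    "MicroParams",
    "DoseEvent",
    "Regimen",
    "InvalidCovariateError",
    "InvalidParameterError",
    "cockcroft_gault",
    "individual_params",
    "concentration_profile",
    "cmax_mod",
    "cmin_24",
    "PARAM_NAMES",
]

#: µmol/L of creatinine per mg/dL
CREATININE_UMOL_PER_MGDL = 88.4

#: population-scale parameter vector layout used throughout the package
PARAM_NAMES = ("vs", "ki", "ks", "k12", "k21")

# branch threshold for the repeated-eigenvalue (alpha == beta) limit formula
_REPEATED_ROOT_RTOL = 1e-9


class InvalidCovariateError(ValueError):
    """Covariate values outside the physiologically valid domain."""


class InvalidParameterError(ValueError):
    """Kinetic parameters outside the valid domain (e.g. Ke <= 0)."""


@dataclass(frozen=True)
class CovariateSet:
    """Patient covariates at one timepoint.

    Parameters
    ----------
    age : float
        Age in years (adults only, >= 18).
    sex : str
        ``"female"`` or ``"male"``.
    body_weight : float
        Body weight in kg.
    serum_creatinine : float
        Serum creatinine in µmol/L.
    """

    age: float
    sex: str
    body_weight: float
    serum_creatinine: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise InvalidCovariateError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.age < 18:
            raise InvalidCovariateError(f"adult model requires age >= 18 y, got {self.age}")
        if not self.body_weight > 0:
            raise InvalidCovariateError(f"body_weight must be > 0 kg, got {self.body_weight}")
        if not self.serum_creatinine > 0:
            raise InvalidCovariateError(
                f"serum_creatinine must be > 0 µmol/L, got {self.serum_creatinine}"
            )

    @property
    def clcr(self) -> float:
        """Cockcroft–Gault creatinine clearance in mL/min (derived)."""
        return cockcroft_gault(self)


@dataclass(frozen=True)
class SupportPoint:
    """One discrete support point of a nonparametric population prior.

    Fields are on the population (covariate-free) scale: ``vs`` in L/kg,
    ``ki`` in 1/h, ``ks`` in 1/h per (mL/min), ``k12``/``k21`` in 1/h, and a
    probability ``weight``.
    """

    vs: float
    ki: float
    ks: float
    k12: float
    k21: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.vs > 0:
            raise InvalidParameterError("vs must be > 0")
        if self.ki < 0 or self.ks < 0 or self.k12 < 0 or self.k21 < 0:
            raise InvalidParameterError("ki, ks, k12, k21 must be >= 0")
        if self.k12 > 0 and not self.k21 > 0:
            raise InvalidParameterError("k21 must be > 0 when k12 > 0")
        if not 0.0 <= self.weight <= 1.0 + 1e-12:
            raise InvalidParameterError(f"weight must lie in [0, 1], got {self.weight}")

    def as_array(self) -> np.ndarray:
        return np.array([self.vs, self.ki, self.ks, self.k12, self.k21])


@dataclass(frozen=True)
class MicroParams:
    """Individual-scale kinetic constants after covariate mapping.

    ``v1`` in L, rate constants in 1/h. ``clearance`` (L/h) is the derived
    product ``ke * v1``.
    """

    v1: float
    ke: float
    k12: float
    k21: float

    def __post_init__(self) -> None:
        if not self.v1 > 0:
            raise InvalidParameterError(f"v1 must be > 0 L, got {self.v1}")
        if not self.ke > 0:
            raise InvalidParameterError(f"ke must be > 0 /h, got {self.ke}")
        if self.k12 < 0 or self.k21 < 0:
            raise InvalidParameterError("k12 and k21 must be >= 0")
        if self.k12 > 0 and not self.k21 > 0:
            raise InvalidParameterError("k21 must be > 0 when k12 > 0 (no trap compartment)")

    @property
    def clearance(self) -> float:
        return self.ke * self.v1


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order IV infusion: start time (h), duration (h), amount (mg)."""

    start_time: float
    infusion_duration: float
    amount: float

    def __post_init__(self) -> None:
        if not self.infusion_duration > 0:
            raise ValueError(f"infusion_duration must be > 0 h, got {self.infusion_duration}")
        if self.amount < 0:
            raise ValueError(f"amount must be >= 0 mg, got {self.amount}")


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of infusion events plus the dosing interval.

    ``interval`` defaults to 24 h (once-daily extended-interval dosing);
    ``n_doses_to_steady_state`` is the number of doses used when a
    steady-state prediction is requested by explicit superposition.
    """

    events: tuple[DoseEvent, ...]
    interval: float = 24.0
    n_doses_to_steady_state: int = 7

    def __post_init__(self) -> None:
        if not self.interval > 0:
            raise ValueError("interval must be > 0 h")
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        starts = [e.start_time for e in events]
        if starts != sorted(starts):
            raise ValueError("dose events must be time-sorted")
        for a, b in zip(events, events[1:]):
            if a.start_time + a.infusion_duration > b.start_time + 1e-12:
                raise ValueError("dose events must not overlap")

    @classmethod
    def once_daily(
        cls,
        dose: float,
        n_doses: int = 1,
        infusion_duration: float = 0.5,
        interval: float = 24.0,
    ) -> "Regimen":
        """Build a once-daily regimen of ``n_doses`` identical infusions."""
        events = tuple(
            DoseEvent(start_time=i * interval, infusion_duration=infusion_duration, amount=dose)
            for i in range(n_doses)
        )
        return cls(events=events, interval=interval)


def cockcroft_gault(cov: CovariateSet) -> float:
    """Creatinine clearance (mL/min) by the Cockcroft–Gault equation.

    ``CLCR = (140 - age) * BW / (72 * SCr[mg/dL])``, times 0.85 for women.
    Serum creatinine is converted from µmol/L (÷ 88.4). No upper cap is
    applied.
    """
    scr_mgdl = cov.serum_creatinine / CREATININE_UMOL_PER_MGDL
    clcr = (140.0 - cov.age) * cov.body_weight / (72.0 * scr_mgdl)
    if cov.sex == "female":
        clcr *= 0.85
    if not clcr > 0:
        raise InvalidCovariateError(f"derived CLCR must be > 0 mL/min, got {clcr}")
    return clcr


def creatinine_for_clcr(clcr: float, age: float, sex: str, body_weight: float) -> float:
    """Invert Cockcroft–Gault: the serum creatinine (µmol/L) giving ``clcr``.

    Used by the synthetic cohort generator to back-solve creatinine so that
    a drawn clearance round-trips exactly through :func:`cockcroft_gault`.
    """
    if not clcr > 0:
        raise InvalidCovariateError("clcr must be > 0")
    factor = 0.85 if sex == "female" else 1.0
    scr_mgdl = (140.0 - age) * body_weight * factor / (72.0 * clcr)
    return scr_mgdl * CREATININE_UMOL_PER_MGDL


def individual_params(point: SupportPoint, cov: CovariateSet) -> MicroParams:
    """Map a population support point through the covariate model.

    ``v1 = vs * BW`` and ``ke = ki + ks * CLCR``; the intercompartmental
    constants are copied unchanged.
    """
    ke = point.ki + point.ks * cov.clcr
    if not ke > 0:
        raise InvalidParameterError(f"mapped ke must be > 0, got {ke}")
    return MicroParams(v1=point.vs * cov.body_weight, ke=ke, k12=point.k12, k21=point.k21)


# ---------------------------------------------------------------------------
# vectorized closed-form solution
# ---------------------------------------------------------------------------


def _hybrid_constants(ke: np.ndarray, k12: np.ndarray, k21: np.ndarray):
    """Hybrid (macro) constants alpha >= beta with alpha+beta = ke+k12+k21,
    alpha*beta = ke*k21. beta is computed as the product over alpha to avoid
    catastrophic cancellation."""
    s = ke + k12 + k21
    p = ke * k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(alpha > 0, p / alpha, 0.0)
    return alpha, beta


def _g(rate: np.ndarray, t: np.ndarray) -> np.ndarray:
    """(1 - exp(-rate*t)) / rate, with the rate -> 0 limit equal to t."""
    rt = rate * t
    small = np.abs(rate) < 1e-300
    safe_rate = np.where(small, 1.0, rate)
    out = -np.expm1(-rt) / safe_rate
    return np.where(small, t, out)


def _infusion_response(v1, ke, k12, k21, rate, tau):
    """Central concentration response to a never-ending infusion at ``rate``
    (mg/h) that started ``tau`` hours ago (tau clipped at 0). Broadcasts over
    parameter arrays (shape (..., 1)) against time arrays (shape (m,))."""
    alpha, beta = _hybrid_constants(ke, k12, k21)
    tau = np.maximum(tau, 0.0)
    diff = alpha - beta
    repeated = diff <= _REPEATED_ROOT_RTOL * np.maximum(alpha, 1e-300)

    # distinct-root branch
    safe_diff = np.where(repeated, 1.0, diff)
    c1 = (alpha - k21) / safe_diff
    c2 = (k21 - beta) / safe_diff
    distinct = c1 * _g(alpha, tau) + c2 * _g(beta, tau)

    # repeated-root limit: bolus kernel e^{-a t}(1 + (k21-a) t); its integral
    # is g(a,t) + (k21-a) * (1 - (1+a t) e^{-a t}) / a^2
    a = alpha
    safe_a = np.where(a > 0, a, 1.0)
    quad = (1.0 - (1.0 + a * tau) * np.exp(-a * tau)) / (safe_a * safe_a)
    limit = _g(a, tau) + (k21 - a) * quad

    return (rate / v1) * np.where(repeated, limit, distinct)


def profile_matrix(
    v1: np.ndarray,
    ke: np.ndarray,
    k12: np.ndarray,
    k21: np.ndarray,
    events: Sequence[DoseEvent],
    times: np.ndarray,
) -> np.ndarray:
    """Central-compartment concentrations (mg/L) for many parameter sets.

    Parameters are 1-D arrays of equal length n; ``times`` is 1-D of length
    m. Returns an (n, m) matrix by superposition of per-event infusion
    on/off responses.
    """
    v1 = np.atleast_1d(np.asarray(v1, dtype=float))[:, None]
    ke = np.atleast_1d(np.asarray(ke, dtype=float))[:, None]
    k12 = np.atleast_1d(np.asarray(k12, dtype=float))[:, None]
    k21 = np.atleast_1d(np.asarray(k21, dtype=float))[:, None]
    times = np.asarray(times, dtype=float)[None, :]

    out = np.zeros(np.broadcast_shapes(v1.shape, times.shape), dtype=float)
    for ev in events:
        if ev.amount == 0.0:
            continue
        rate = ev.amount / ev.infusion_duration
        tau_on = times - ev.start_time
        tau_off = tau_on - ev.infusion_duration
        out = out + _infusion_response(v1, ke, k12, k21, rate, tau_on)
        out = out - _infusion_response(v1, ke, k12, k21, rate, tau_off)
    return np.maximum(out, 0.0)


def concentration_profile(
    params: MicroParams, regimen: Regimen, times: Sequence[float]
) -> np.ndarray:
    """Central-compartment concentration (mg/L) at the requested times (h).

    Closed-form bi-exponential infusion solution, superposed over all dose
    events of the regimen; continuous at infusion end and exact for the
    repeated-eigenvalue corner case via the analytic limit.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    return profile_matrix(
        np.array([params.v1]),
        np.array([params.ke]),
        np.array([params.k12]),
        np.array([params.k21]),
        regimen.events,
        times,
    )[0]


def _standard_events(dose: float, tinf: float, interval: float, n_doses: int):
    return [
        DoseEvent(start_time=i * interval, infusion_duration=tinf, amount=dose)
        for i in range(n_doses)
    ]


def cmax_mod_matrix(
    v1, ke, k12, k21, dose: float, *, tinf: float = 0.5, offset: float = 0.5,
    interval: float = 24.0, steady_state: bool = True, n_doses: int = 7
) -> np.ndarray:
    """Vectorized standardized peak for many parameter sets (see :func:`cmax_mod`)."""
    n = n_doses if steady_state else 1
    events = _standard_events(dose, tinf, interval, n)
    t_eval = (n - 1) * interval + tinf + offset
    return profile_matrix(v1, ke, k12, k21, events, np.array([t_eval]))[:, 0]


def cmin_24_matrix(
    v1, ke, k12, k21, dose: float, *, tinf: float = 0.5,
    interval: float = 24.0, steady_state: bool = True, n_doses: int = 7
) -> np.ndarray:
    """Vectorized 24-h trough for many parameter sets (see :func:`cmin_24`)."""
    n = n_doses if steady_state else 1
    events = _standard_events(dose, tinf, interval, n)
    t_eval = (n - 1) * interval + interval
    return profile_matrix(v1, ke, k12, k21, events, np.array([t_eval]))[:, 0]


def cmax_mod(
    params: MicroParams,
    dose: float,
    *,
    tinf: float = 0.5,
    offset: float = 0.5,
    interval: float = 24.0,
    steady_state: bool = True,
    n_doses: int = 7,
) -> float:
    """Model-standardized peak: concentration 30 min after the end of a
    standardized 30-min infusion (t = 1.0 h after infusion start), regardless
    of the actually recorded infusion and sampling times.

    With ``steady_state`` (default) the value is taken after ``n_doses``
    once-daily doses by explicit superposition.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0 mg")
    return float(
        cmax_mod_matrix(
            np.array([params.v1]), np.array([params.ke]),
            np.array([params.k12]), np.array([params.k21]),
            dose, tinf=tinf, offset=offset, interval=interval,
            steady_state=steady_state, n_doses=n_doses,
        )[0]
    )


def cmin_24(
    params: MicroParams,
    dose: float,
    *,
    tinf: float = 0.5,
    interval: float = 24.0,
    steady_state: bool = True,
    n_doses: int = 7,
) -> float:
    """Trough 24 h after infusion start (immediately pre next dose), for a
    once-daily regimen of ``dose`` mg, at steady state by default."""
    if dose < 0:
        raise ValueError("dose must be >= 0 mg")
    return float(
        cmin_24_matrix(
            np.array([params.v1]), np.array([params.ke]),
            np.array([params.k12]), np.array([params.k21]),
            dose, tinf=tinf, interval=interval,
            steady_state=steady_state, n_doses=n_doses,
        )[0]
    )
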
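"""Target-driven once-daily dose recommendation on a 25-mg grid.

The dosing service reports three doses, one per bound of the peak target
ladder (30, 35, 40 mg/L of standardized peak Cmax_mod), each checked against
the 24-h trough limit of 0.5 mg/L. The continuous optimum minimizes the
posterior-expected squared deviation of Cmax_mod from the target; because
the kinetics are linear in dose, each support point contributes a unit
response a_i (mg/L per mg) and the minimizer has the closed form

    D* = target * sum(w_i a_i) / sum(w_i a_i^2).

Doses are then rounded UP to the next 25-mg multiple (the available
presentations in France), and the predicted steady-state Cmax_mod / Cmin24
at the grid dose are reported with warnings for trough violations or
rounding that pushes the peak out of the 30-40 mg/L window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .bayes import Posterior
from .pk import CovariateSet, cmax_mod_matrix, cmin_24_matrix

__all__ = [
    "TargetSpec",
    "TargetRecommendation",
    "DoseRecommendation",
    "NoResponseError",
    "predict_for_dose",
    "optimal_dose",
    "round_dose",
    "recommend",
]


class NoResponseError(RuntimeError):
    """No support point produces any concentration response (all a_i = 0)."""


@dataclass(frozen=True)
class TargetSpec:
    """Concentration targets and dosing conventions for once-daily tobramycin.

    The peak window 30-40 mg/L operationalizes a Cmax/MIC target of 8-10
    against the 4 mg/L susceptibility breakpoint for P. aeruginosa
    (``mic_breakpoint`` is a rationale constant, not used in computation).
    """

    cmax_low: float = 30.0
    cmax_mid: float = 35.0
    cmax_high: float = 40.0
    cmin_limit: float = 0.5
    dose_grid: float = 25.0
    standard_tinf: float = 0.5
    cmax_offset: float = 0.5
    interval: float = 24.0
    n_doses_to_steady_state: int = 7
    mic_breakpoint: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.cmax_low < self.cmax_mid < self.cmax_high):
            raise ValueError("targets must satisfy 0 < low < mid < high")
        if min(self.cmin_limit, self.dose_grid, self.standard_tinf, self.cmax_offset) <= 0:
            raise ValueError("cmin_limit, dose_grid, standard_tinf, cmax_offset must be > 0")

    @property
    def targets(self) -> tuple[float, float, float]:
        return (self.cmax_low, self.cmax_mid, self.cmax_high)


@dataclass(frozen=True)
class TargetRecommendation:
    """One row of the report: target level with unrounded/grid dose and
    predicted steady-state exposures at the grid dose."""

    target: float
    unrounded_dose: float
    grid_dose: float
    predicted_cmax_mod: float
    predicted_cmin_24: float
    cmin_ok: bool


@dataclass(frozen=True)
class DoseRecommendation:
    """Three grid-rounded doses for the 30/35/40 mg/L target ladder."""

    per_target: tuple[TargetRecommendation, ...]
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "recommendations": [
                {
                    "target_mg_L": r.target,
                    "unrounded_dose_mg": r.unrounded_dose,
                    "grid_dose_mg": r.grid_dose,
                    "predicted_cmax_mod_mg_L": r.predicted_cmax_mod,
                    "predicted_cmin_24_mg_L": r.predicted_cmin_24,
                    "cmin_ok": r.cmin_ok,
                }
                for r in self.per_target
            ],
            "warnings": list(self.warnings),
        }

    def to_text(self) -> str:
        """Human-readable block mirroring the PK report sent to physicians
        (concentrations to 0.1 mg/L, doses to whole mg)."""
        lines = ["Once-daily tobramycin dose recommendations", "-" * 43]
        for r in self.per_target:
            lines.append(
                f"target Cmax_mod {r.target:4.0f} mg/L : {r.grid_dose:5.0f} mg"
                f"  (predicted peak {r.predicted_cmax_mod:.1f} mg/L,"
                f" 24-h trough {r.predicted_cmin_24:.1f} mg/L"
                f"{'' if r.cmin_ok else ', TROUGH >= 0.5 mg/L'})"
            )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def _unit_responses(post: Posterior, cov: CovariateSet, spec: TargetSpec):
    """Per-support-point unit responses: Cmax_mod and Cmin24 per mg of dose,
    at steady state under the standardized infusion."""
    theta = post.theta
    clcr = cov.clcr
    v1 = theta[:, 0] * cov.body_weight
    ke = theta[:, 1] + theta[:, 2] * clcr
    common = dict(
        tinf=spec.standard_tinf,
        interval=spec.interval,
        steady_state=True,
        n_doses=spec.n_doses_to_steady_state,
    )
    a = cmax_mod_matrix(
        v1, ke, theta[:, 3], theta[:, 4], 1.0, offset=spec.cmax_offset, **common
    )
    b = cmin_24_matrix(v1, ke, theta[:, 3], theta[:, 4], 1.0, **common)
    return a, b


def predict_for_dose(
    post: Posterior, cov: CovariateSet, dose: float, spec: TargetSpec | None = None
) -> tuple[float, float]:
    """Posterior-expected (Cmax_mod, Cmin24) at steady state for a dose.

    Expectations are taken over the support points (multiple-model
    prediction), under the standardized 0.5-h infusion.
    """
    spec = spec or TargetSpec()
    if dose < 0:
        raise ValueError("dose must be >= 0 mg")
    a, b = _unit_responses(post, cov, spec)
    return float(dose * (post.weights @ a)), float(dose * (post.weights @ b))


def optimal_dose(
    post: Posterior, cov: CovariateSet, target: float, spec: TargetSpec | None = None
) -> float:
    """Continuous dose minimizing posterior-expected squared deviation of
    Cmax_mod from ``target``: D* = target·Σw a / Σw a²."""
    spec = spec or TargetSpec()
    if target <= 0:
        raise ValueError("target must be > 0 mg/L")
    a, _ = _unit_responses(post, cov, spec)
    denom = float(post.weights @ (a * a))
    if denom <= 0:
        raise NoResponseError("no support point produces a concentration response")
    return target * float(post.weights @ a) / denom


def round_dose(dose: float, grid: float = 25.0) -> float:
    """Round UP to the next grid multiple; exact multiples are unchanged."""
    if dose <= 0:
        raise ValueError("dose must be > 0 mg")
    if grid <= 0:
        raise ValueError("grid must be > 0 mg")
    n = math.ceil(dose / grid - 1e-9)
    return max(n, 1) * grid


def recommend(
    post: Posterior, cov: CovariateSet, spec: TargetSpec | None = None
) -> DoseRecommendation:
    """Compute the three-dose report for the target ladder.

    For each target: continuous optimum → 25-mg ceiling → predicted
    steady-state exposures at the grid dose. A warning is appended when the
    expected 24-h trough breaches 0.5 mg/L or when grid rounding pushes the
    predicted peak out of the 30-40 mg/L window.
    """
    spec = spec or TargetSpec()
    a, b = _unit_responses(post, cov, spec)
    ea = float(post.weights @ a)
    ea2 = float(post.weights @ (a * a))
    eb = float(post.weights @ b)
    if ea2 <= 0:
        raise NoResponseError("no support point produces a concentration response")
    rows = []
    warnings: list[str] = []
    for target in spec.targets:
        d_star = target * ea / ea2
        d_grid = round_dose(d_star, spec.dose_grid)
        cmax = d_grid * ea
        cmin = d_grid * eb
        cmin_ok = cmin < spec.cmin_limit
        rows.append(
            TargetRecommendation(
                target=target,
                unrounded_dose=d_star,
                grid_dose=d_grid,
                predicted_cmax_mod=cmax,
                predicted_cmin_24=cmin,
                cmin_ok=cmin_ok,
            )
        )
        if not cmin_ok:
            warnings.append(
                f"target {target:g} mg/L: expected 24-h trough {cmin:.2f} mg/L >= "
                f"{spec.cmin_limit:g} mg/L (interval extension not attempted)"
            )
        if not (spec.cmax_low <= cmax <= spec.cmax_high):
            warnings.append(
                f"target {target:g} mg/L: predicted Cmax_mod {cmax:.1f} mg/L falls "
                f"outside [{spec.cmax_low:g}, {spec.cmax_high:g}] after grid rounding"
            )
    return DoseRecommendation(per_target=tuple(rows), warnings=tuple(warnings))
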
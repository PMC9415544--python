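"""Per-course TDM pipeline orchestration and cohort-level analytics.

One course = one patient's 14-day once-daily tobramycin treatment with a
single TDM occasion (peak + trough on day 3 or 4). `run_course` chains BLQ
preprocessing, the Bayes update (falling back to the hybrid fit when the
standard fit is inadequate), point estimation and fit diagnostics, and the
three-dose recommendation.

Cohort analytics reproduce the study-report tables: demographic summaries,
target-attainment bins for the standardized peak and 24-h trough,
dose-change classification stratified by estimated-peak bin, the paired
Wilcoxon tests on doses and serum creatinine, and the >= 50%-creatinine-rise
marker of acute kidney injury (AKI).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .bayes import (
    AssayErrorModel,
    DegenerateFitError,
    FitReport,
    Observation,
    UnfittableCourseError,
    fit_is_inadequate,
    fit_metrics,
    hybrid_fit,
    point_estimates,
    posterior_weights,
    preprocess_blq,
)
from .design import DoseRecommendation, TargetSpec, recommend
from .pk import CovariateSet, Regimen
from .priors import DiscretePrior

__all__ = [
    "CourseRecord",
    "CourseResult",
    "CohortSummary",
    "run_course",
    "run_cohort",
    "attainment_class",
    "dose_change_class",
    "aki_flag",
    "wilcoxon_signed_rank",
    "cohort_summary",
]


@dataclass
class CourseRecord:
    """One tobramycin course: dosing history, observations and covariates.

    ``covariates_end`` is None when the end-of-therapy creatinine was not
    drawn; such courses are unevaluable for the AKI marker and excluded from
    the paired creatinine test. ``accepted_dose`` is the dose the physician
    finally selected (may be absent).
    """

    patient_id: str
    course_id: str
    covariates_start: CovariateSet
    regimen: Regimen
    observations: list[Observation]
    initial_dose: float
    covariates_end: CovariateSet | None = None
    accepted_dose: float | None = None

    def __post_init__(self) -> None:
        if not self.initial_dose > 0:
            raise ValueError("initial_dose must be > 0 mg")
        if self.regimen.events:
            t_end = max(e.start_time + e.infusion_duration for e in self.regimen.events)
            for obs in self.observations:
                if obs.time > t_end + self.regimen.interval + 1e-9:
                    raise ValueError(
                        f"observation at t={obs.time} h lies outside the course span"
                    )


@dataclass(frozen=True)
class CourseResult:
    """Pipeline output for one course."""

    course: CourseRecord
    fit: FitReport
    recommendation: DoseRecommendation


def run_course(
    course: CourseRecord,
    prior: DiscretePrior,
    err: AssayErrorModel | None = None,
    spec: TargetSpec | None = None,
    *,
    hybrid_seed: int = 0,
) -> tuple[FitReport, DoseRecommendation]:
    """Run the full MIPD pipeline on one course.

    BLQ substitution → posterior weights (hybrid refit on trigger) → point
    estimates and fit metrics → three-dose recommendation. Deterministic
    given its inputs.
    """
    err = err or AssayErrorModel()
    spec = spec or TargetSpec()
    cov = course.covariates_start
    obs = preprocess_blq(course.observations)
    notes: list[str] = []
    if obs and all(o.blq for o in obs):
        notes.append("all observations below the limit of quantification; "
                     "fit carries little individual information")
    try:
        post = posterior_weights(prior, cov, course.regimen, obs, err)
        if obs and fit_is_inadequate(post, cov, course.regimen, obs):
            post = hybrid_fit(prior, cov, course.regimen, obs, err, seed=hybrid_seed)
            notes.append("hybrid fit used (standard fit inadequate)")
    except DegenerateFitError:
        post = hybrid_fit(prior, cov, course.regimen, obs, err, seed=hybrid_seed)
        notes.append("hybrid fit used (standard fit degenerate)")
    except UnfittableCourseError as exc:
        raise UnfittableCourseError(f"course {course.course_id}: {exc}") from exc

    est = point_estimates(post, cov, course.regimen, obs)
    metrics = fit_metrics([o.concentration for o in obs], list(est.predictions))
    fit = FitReport(
        observations=tuple(obs),
        estimates=est,
        metrics=metrics,
        posterior=post,
        warnings=tuple(notes),
    )
    rec = recommend(post, cov, spec)
    return fit, rec


def run_cohort(
    courses: Sequence[CourseRecord],
    prior: DiscretePrior,
    err: AssayErrorModel | None = None,
    spec: TargetSpec | None = None,
) -> list[CourseResult]:
    """Run the pipeline over every course, preserving order."""
    out = []
    for course in courses:
        fit, rec = run_course(course, prior, err, spec)
        out.append(CourseResult(course=course, fit=fit, recommendation=rec))
    return out


def attainment_class(
    cmax_mod: float, cmin: float, spec: TargetSpec | None = None
) -> tuple[str, bool]:
    """Classify a (standardized peak, 24-h trough) pair against the targets.

    Peak bins: ``below`` (< 30), ``in-range`` (closed interval [30, 40]),
    ``above`` (> 40); the trough criterion is strict (< 0.5 mg/L).
    """
    spec = spec or TargetSpec()
    if cmax_mod < 0 or cmin < 0:
        raise ValueError("concentrations must be >= 0")
    if cmax_mod < spec.cmax_low:
        bin_ = "below"
    elif cmax_mod <= spec.cmax_high:
        bin_ = "in-range"
    else:
        bin_ = "above"
    return bin_, cmin < spec.cmin_limit


def dose_change_class(initial: float, accepted: float | None) -> tuple[str, float | None]:
    """Classify a dose adjustment (exact comparison) with its delta in mg.

    A missing accepted dose is recorded as ``not adjusted`` with delta None;
    such courses are excluded from the paired dose test.
    """
    if not initial > 0:
        raise ValueError("initial dose must be > 0 mg")
    if accepted is None:
        return "not adjusted", None
    if not accepted > 0:
        raise ValueError("accepted dose must be > 0 mg")
    delta = accepted - initial
    if delta > 0:
        return "increase", delta
    if delta < 0:
        return "decrease", delta
    return "unchanged", 0.0


def aki_flag(scr_start: float, scr_end: float | None) -> bool | None:
    """AKI marker: serum creatinine rise of >= 50% from baseline.

    Returns None (unevaluable) when the end-of-therapy creatinine is
    missing; missing values are never imputed.
    """
    if not scr_start > 0:
        raise ValueError("baseline creatinine must be > 0")
    if scr_end is None:
        return None
    if not scr_end > 0:
        raise ValueError("end creatinine must be > 0")
    return (scr_end - scr_start) / scr_start >= 0.5


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon's original convention); the exact
    null distribution is used for n <= 25 without ties, otherwise the normal
    approximation with tie and continuity corrections. Returns
    (statistic, p_value); raises ValueError when all differences are zero.
    """
    before = np.array([p[0] for p in pairs], dtype=float)
    after = np.array([p[1] for p in pairs], dtype=float)
    diffs = after - before
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    has_ties = np.unique(np.abs(diffs)).size < diffs.size
    method = "exact" if (diffs.size <= 25 and not has_ties) else "approx"
    res = scipy.stats.wilcoxon(
        diffs, zero_method="wilcox", correction=True, alternative="two-sided",
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


@dataclass
class CohortSummary:
    """Study-report style cohort summary (see :func:`cohort_summary`)."""

    n_courses: int
    n_patients: int
    demographics: dict
    attainment: dict
    dose_change: dict
    aki: dict
    paired_tests: dict
    missing_end_creatinine: int

    def to_dict(self) -> dict:
        return {
            "n_courses": self.n_courses,
            "n_patients": self.n_patients,
            "demographics": self.demographics,
            "attainment": self.attainment,
            "dose_change": self.dose_change,
            "aki": self.aki,
            "paired_tests": self.paired_tests,
            "missing_end_creatinine": self.missing_end_creatinine,
        }


def cohort_summary(
    results: Sequence[CourseResult], spec: TargetSpec | None = None
) -> CohortSummary:
    """Assemble attainment, dose-change, AKI and paired-test summaries.

    Attainment after initial dosing uses each course's *estimated*
    standardized peak and 24-h trough at the initial dose (posterior
    expectations); "expected attainment" is the proportion of accepted doses
    whose predicted peak lies in [30, 40] mg/L. All proportions are
    recomputed from the per-course classification lists.
    """
    if not results:
        raise ValueError("at least one processed course is required")
    spec = spec or TargetSpec()

    from .design import predict_for_dose  # local import to avoid cycle at module load

    courses = [r.course for r in results]
    n_patients = len({c.patient_id for c in courses})

    weights = [c.covariates_start.body_weight for c in courses]
    ages = [c.covariates_start.age for c in courses]
    clcrs = [c.covariates_start.clcr for c in courses]
    doses_mg = [c.initial_dose for c in courses]
    doses_mgkg = [c.initial_dose / c.covariates_start.body_weight for c in courses]

    # estimated exposures at the initial dose
    bins = []
    cmin_ok_flags = []
    est_cmax_initial = []
    for r in results:
        cmax, cmin = predict_for_dose(
            r.fit.posterior, r.course.covariates_start, r.course.initial_dose, spec
        )
        est_cmax_initial.append(cmax)
        b, ok = attainment_class(cmax, cmin, spec)
        bins.append(b)
        cmin_ok_flags.append(ok)
    n = len(results)
    attainment = {
        "cmax_mod_below": bins.count("below") / n,
        "cmax_mod_in_range": bins.count("in-range") / n,
        "cmax_mod_above": bins.count("above") / n,
        "cmin_below_limit": sum(cmin_ok_flags) / n,
    }

    # dose changes, stratified by estimated-peak bin
    changes = [dose_change_class(c.initial_dose, c.accepted_dose) for c in courses]
    labels = [c[0] for c in changes]
    by_bin: dict[str, dict] = {}
    for bin_name in ("below", "in-range", "above"):
        idx = [i for i, b in enumerate(bins) if b == bin_name]
        deltas_up = [changes[i][1] for i in idx if labels[i] == "increase"]
        deltas_down = [-changes[i][1] for i in idx if labels[i] == "decrease"]
        by_bin[bin_name] = {
            "n": len(idx),
            "unchanged": sum(labels[i] == "unchanged" for i in idx),
            "increase": {
                "n": len(deltas_up),
                "median": float(np.median(deltas_up)) if deltas_up else None,
                "range": [min(deltas_up), max(deltas_up)] if deltas_up else None,
            },
            "decrease": {
                "n": len(deltas_down),
                "median": float(np.median(deltas_down)) if deltas_down else None,
                "range": [min(deltas_down), max(deltas_down)] if deltas_down else None,
            },
        }
    accepted_pred = [
        predict_for_dose(r.fit.posterior, r.course.covariates_start,
                         r.course.accepted_dose, spec)[0]
        for r in results
        if r.course.accepted_dose is not None
    ]
    expected_attainment = (
        sum(spec.cmax_low <= c <= spec.cmax_high for c in accepted_pred) / len(accepted_pred)
        if accepted_pred else math.nan
    )
    dose_change = {
        "unchanged": labels.count("unchanged"),
        "increase": labels.count("increase"),
        "decrease": labels.count("decrease"),
        "not_adjusted": labels.count("not adjusted"),
        "by_estimated_cmax_bin": by_bin,
        "expected_attainment_at_accepted_dose": expected_attainment,
    }

    # AKI
    aki_flags = [
        aki_flag(
            c.covariates_start.serum_creatinine,
            c.covariates_end.serum_creatinine if c.covariates_end else None,
        )
        for c in courses
    ]
    n_eval = sum(f is not None for f in aki_flags)
    n_aki = sum(bool(f) for f in aki_flags if f is not None)
    missing = sum(f is None for f in aki_flags)
    aki = {
        "n_evaluable": n_eval,
        "n_aki": n_aki,
        "proportion": (n_aki / n_eval) if n_eval else math.nan,
    }

    # paired tests
    dose_pairs = [
        (c.initial_dose, c.accepted_dose) for c in courses if c.accepted_dose is not None
    ]
    scr_pairs = [
        (c.covariates_start.serum_creatinine, c.covariates_end.serum_creatinine)
        for c in courses
        if c.covariates_end is not None
    ]
    paired_tests: dict = {}
    for name, pairs in (("dose", dose_pairs), ("serum_creatinine", scr_pairs)):
        if len(pairs) >= 2 and any(a != b for a, b in pairs):
            stat, p = wilcoxon_signed_rank(pairs)
            paired_tests[name] = {"n": len(pairs), "statistic": stat, "p_value": p}
        else:
            paired_tests[name] = {"n": len(pairs), "statistic": None, "p_value": None}

    wm, ws = _mean_sd(weights)
    am, asd = _mean_sd(ages)
    cm, cs = _mean_sd(clcrs)
    dm, ds = _mean_sd(doses_mg)
    dkm, dks = _mean_sd(doses_mgkg)
    demographics = {
        "weight_kg": {"mean": wm, "sd": ws},
        "age_y": {"mean": am, "sd": asd},
        "clcr_mL_min": {"mean": cm, "sd": cs},
        "initial_dose_mg": {"mean": dm, "sd": ds},
        "initial_dose_mg_kg": {"mean": dkm, "sd": dks},
    }

    return CohortSummary(
        n_courses=n,
        n_patients=n_patients,
        demographics=demographics,
        attainment=attainment,
        dose_change=dose_change,
        aki=aki,
        paired_tests=paired_tests,
        missing_end_creatinine=missing,
    )
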
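"""Synthetic TDM cohort generator emulating the study population.

Generates virtual adult CF patients (weight 57.5 ± 12.3 kg, age 32.4 ± 10 y,
69% women, creatinine clearance 112.7 ± 28.4 mL/min with serum creatinine
back-solved through Cockcroft–Gault), physician-style initial dosing
(9.16 ± 1.42 mg/kg rounded to the 25-mg grid), realistic dosing/sampling
schedules with jitter (infusion 35.9 ± 7.4 min; peak drawn 32.1 ± 8.9 min
after infusion end, truncated to the observed 4–69 min extremes), noisy
observations with LLOQ censoring at 0.2 mg/L, and end-of-therapy creatinine
with a small AKI probability. Ground truth (the support point each course
was simulated from and its noiseless exposures) is returned alongside, so
every pipeline stage is testable with no external data.

A ``mismatch_vs_factor`` > 1 inflates the true central volume relative to
the analysis prior, reproducing the under-target regime in which most
courses sit below the 30 mg/L standardized-peak target at ~9 mg/kg dosing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .bayes import LLOQ_MG_L, Observation
from .cohort import CourseRecord
from .pk import (
    CovariateSet,
    DoseEvent,
    MicroParams,
    Regimen,
    SupportPoint,
    cmax_mod,
    cmin_24,
    concentration_profile,
    creatinine_for_clcr,
    individual_params,
)
from .priors import DiscretePrior

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_patient",
    "sample_true_params",
    "simulate_course",
    "end_creatinine",
    "generate_cohort",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the virtual cohort.

    Moments mirror the study's cohort tables; truncation bounds exclude
    physiologically impossible adults.
    """

    n_patients: int = 61
    repeat_course_fraction: float = 17 / 61
    n_repeat_courses: int | None = 17  # deterministic count; None -> Bernoulli
    seed: int = 0

    weight_mean: float = 57.5
    weight_sd: float = 12.3
    # symmetric about the mean so truncation leaves the mean unbiased; CF
    # adults are characteristically underweight (cohort BMI ~21 kg/m2)
    weight_bounds: tuple[float, float] = (35.0, 80.0)
    age_mean: float = 32.4
    age_sd: float = 10.0
    age_bounds: tuple[float, float] = (18.0, 65.0)
    female_fraction: float = 53 / 77
    clcr_mean: float = 112.7
    clcr_sd: float = 28.4
    clcr_bounds: tuple[float, float] = (30.0, 200.0)

    initial_dose_mean_mg_kg: float = 9.16
    initial_dose_sd_mg_kg: float = 1.42
    n_days: int = 14
    infusion_mean_min: float = 35.9
    infusion_sd_min: float = 7.4
    infusion_bounds_min: tuple[float, float] = (20.0, 60.0)
    peak_delay_mean_min: float = 32.1
    peak_delay_sd_min: float = 8.9
    peak_delay_bounds_min: tuple[float, float] = (4.0, 69.0)
    tdm_days: tuple[int, ...] = (3, 4)

    noise_cv: float = 0.04
    lloq: float = LLOQ_MG_L

    aki_probability: float = 0.013
    scr_end_log_sd: float = 0.12
    missing_end_fraction: float = 8 / 77

    mismatch_vs_factor: float = 1.0
    param_jitter_log_sd: float = 0.0  # multiplicative log-normal jitter on truth

    def __post_init__(self) -> None:
        for name in ("weight_sd", "age_sd", "clcr_sd", "initial_dose_sd_mg_kg",
                     "infusion_sd_min", "peak_delay_sd_min", "noise_cv",
                     "scr_end_log_sd", "param_jitter_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("repeat_course_fraction", "female_fraction",
                     "aki_probability", "missing_end_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("weight_bounds", "age_bounds", "clcr_bounds",
                     "infusion_bounds_min", "peak_delay_bounds_min"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered")


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth for one simulated course."""

    course_id: str
    point: SupportPoint
    micro: MicroParams
    regimen: Regimen
    true_cmax_mod_initial: float
    true_cmin_24_initial: float

    def concentration(self, times) -> np.ndarray:
        """Noiseless concentration profile of the course."""
        return concentration_profile(self.micro, self.regimen, times)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  bounds: tuple[float, float]) -> float:
    """Truncated normal draw by rejection (deterministic given the rng state)."""
    if sd == 0:
        return float(min(max(mean, bounds[0]), bounds[1]))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    raise RuntimeError("truncated-normal rejection failed; check bounds")


def generate_patient(cfg: SynthConfig, rng: np.random.Generator) -> CovariateSet:
    """Draw one virtual patient; serum creatinine is back-solved so the
    derived Cockcroft–Gault clearance equals the drawn value exactly."""
    weight = _trunc_normal(rng, cfg.weight_mean, cfg.weight_sd, cfg.weight_bounds)
    age = _trunc_normal(rng, cfg.age_mean, cfg.age_sd, cfg.age_bounds)
    sex = "female" if rng.random() < cfg.female_fraction else "male"
    clcr = _trunc_normal(rng, cfg.clcr_mean, cfg.clcr_sd, cfg.clcr_bounds)
    scr = creatinine_for_clcr(clcr, age=age, sex=sex, body_weight=weight)
    return CovariateSet(age=age, sex=sex, body_weight=weight, serum_creatinine=scr)


def sample_true_params(
    prior: DiscretePrior, rng: np.random.Generator, *, jitter_log_sd: float = 0.0
) -> SupportPoint:
    """Draw a true parameter vector from the prior (categorical by weight),
    optionally log-normally jittered for continuous-truth scenarios."""
    idx = rng.choice(len(prior), p=prior.weights)
    row = prior.theta[idx].copy()
    if jitter_log_sd > 0:
        row = row * np.exp(rng.normal(0.0, jitter_log_sd, size=row.size))
    return SupportPoint(*row, weight=1.0)


def end_creatinine(
    scr_start: float, cfg: SynthConfig, rng: np.random.Generator
) -> float | None:
    """Draw the end-of-therapy serum creatinine (µmol/L), or None if missing.

    With probability ``aki_probability`` the value rises by a uniform 50-100%
    (an AKI by construction); otherwise it moves log-symmetrically with SD
    calibrated so the cohort clearance-change SD matches the study's
    ~18 mL/min.
    """
    if not scr_start > 0:
        raise ValueError("scr_start must be > 0")
    if rng.random() < cfg.missing_end_fraction:
        return None
    if rng.random() < cfg.aki_probability:
        return scr_start * rng.uniform(1.5, 2.0)
    return scr_start * math.exp(rng.normal(0.0, cfg.scr_end_log_sd))


def simulate_course(
    patient: CovariateSet,
    truth_point: SupportPoint,
    cfg: SynthConfig,
    rng: np.random.Generator,
    *,
    patient_id: str = "P001",
    course_id: str = "C001",
) -> tuple[CourseRecord, SynthTruth]:
    """Simulate one 14-day once-daily course with a single TDM occasion.

    The TDM-day infusion gets its actual (jittered) duration; the peak is
    drawn a jittered delay after infusion end and the trough 24 h after that
    infusion's start. Observed concentrations carry proportional noise and
    are BLQ-flagged below the LLOQ (the measured value is kept; downstream
    preprocessing substitutes half the LLOQ).
    """
    micro = individual_params(truth_point, patient)
    # physicians round to the NEAREST 25 mg presentation (the ceiling rule is
    # specific to the MIPD recommendation); keeps the cohort mean at ~9.16 mg/kg
    raw = max(rng.normal(cfg.initial_dose_mean_mg_kg, cfg.initial_dose_sd_mg_kg), 1.0) \
        * patient.body_weight
    dose = max(round(raw / 25.0), 1) * 25.0

    tdm_day = int(rng.choice(np.asarray(cfg.tdm_days)))
    tdm_idx = tdm_day - 1  # 0-based infusion index of the TDM occasion
    tinf_actual_h = _trunc_normal(
        rng, cfg.infusion_mean_min, cfg.infusion_sd_min, cfg.infusion_bounds_min
    ) / 60.0
    peak_delay_h = _trunc_normal(
        rng, cfg.peak_delay_mean_min, cfg.peak_delay_sd_min, cfg.peak_delay_bounds_min
    ) / 60.0

    events = tuple(
        DoseEvent(
            start_time=i * 24.0,
            infusion_duration=tinf_actual_h if i == tdm_idx else 0.5,
            amount=dose,
        )
        for i in range(cfg.n_days)
    )
    regimen = Regimen(events=events)

    t0 = tdm_idx * 24.0
    t_peak = t0 + tinf_actual_h + peak_delay_h
    t_trough = t0 + 24.0
    noiseless = concentration_profile(micro, regimen, [t_peak, t_trough])

    observations = []
    for t, c_true, role in ((t_peak, noiseless[0], "peak"), (t_trough, noiseless[1], "trough")):
        c_obs = max(c_true * (1.0 + rng.normal(0.0, cfg.noise_cv)), 0.0)
        observations.append(
            Observation(time=t, concentration=c_obs, blq=c_obs < cfg.lloq, role=role)
        )

    scr_end = end_creatinine(patient.serum_creatinine, cfg, rng)
    cov_end = None if scr_end is None else replace(patient, serum_creatinine=scr_end)

    course = CourseRecord(
        patient_id=patient_id,
        course_id=course_id,
        covariates_start=patient,
        covariates_end=cov_end,
        regimen=regimen,
        observations=observations,
        initial_dose=dose,
    )
    truth = SynthTruth(
        course_id=course_id,
        point=truth_point,
        micro=micro,
        regimen=regimen,
        true_cmax_mod_initial=cmax_mod(micro, dose),
        true_cmin_24_initial=cmin_24(micro, dose),
    )
    return course, truth


def generate_cohort(
    cfg: SynthConfig, prior: DiscretePrior
) -> tuple[list[CourseRecord], list[SynthTruth]]:
    """Generate the full virtual cohort, fully reproducible from cfg.seed.

    True parameters are drawn from ``prior`` (with ``vs`` scaled by
    ``mismatch_vs_factor``); patients selected for a repeat course reuse
    their first course's true parameters (PK is a patient property) but
    redraw baseline creatinine.
    """
    rng = np.random.default_rng(cfg.seed)
    courses: list[CourseRecord] = []
    truths: list[SynthTruth] = []

    if cfg.n_repeat_courses is not None:
        n_repeat = min(cfg.n_repeat_courses, cfg.n_patients)
        repeat_ids = set(
            rng.choice(cfg.n_patients, size=n_repeat, replace=False).tolist()
        )
    else:
        repeat_ids = {
            i for i in range(cfg.n_patients) if rng.random() < cfg.repeat_course_fraction
        }

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        patient = generate_patient(cfg, rng)
        point = sample_true_params(prior, rng, jitter_log_sd=cfg.param_jitter_log_sd)
        if cfg.mismatch_vs_factor != 1.0:
            point = SupportPoint(
                vs=point.vs * cfg.mismatch_vs_factor,
                ki=point.ki, ks=point.ks, k12=point.k12, k21=point.k21,
            )
        course, truth = simulate_course(
            patient, point, cfg, rng, patient_id=pid, course_id=f"{pid}-1"
        )
        courses.append(course)
        truths.append(truth)
        if i in repeat_ids:
            # second course weeks later: same kinetics, fresh renal function
            clcr = _trunc_normal(rng, cfg.clcr_mean, cfg.clcr_sd, cfg.clcr_bounds)
            scr = creatinine_for_clcr(
                clcr, age=patient.age, sex=patient.sex, body_weight=patient.body_weight
            )
            patient2 = replace(patient, serum_creatinine=scr)
            course2, truth2 = simulate_course(
                patient2, point, cfg, rng, patient_id=pid, course_id=f"{pid}-2"
            )
            courses.append(course2)
            truths.append(truth2)
    return courses, truths
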
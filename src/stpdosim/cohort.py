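"""Virtual patient cohort with the kinetic structure of a PRRT dosimetry study.

No real post-therapy images are distributed with this package, so agreement
between dosimetry methods is studied on a simulated cohort whose kinetics
mirror a typical [177Lu]Lu-DOTA-TATE population:

* each patient has a latent per-kidney effective half-life drawn from a
  truncated Normal (default 56 +- 13 h on [25, 110] h; the truncation keeps
  half-lives physical while preserving the stated mean and SD);
* left and right kidney half-lives are correlated (default rho = 0.8) since
  both kidneys share the patient's physiology;
* each therapy cycle perturbs the half-life multiplicatively (mean-one
  lognormal, default CV 8%) to represent genuine inter-cycle kinetic change;
* the time-zero activity A0 is drawn per kidney-cycle (default
  Normal(100, 20) MBq, truncated positive);
* scans follow a day-0 / day-4 / day-7 schedule (default 4 h, 96 h, 168 h
  post-administration, with an optional jitter window for the day-4 scan and
  per-time-point missingness);
* measured activities are the true curve times mean-one lognormal
  measurement noise (default CV 6%, the repeatability scale of quantitative
  Lu-177 SPECT).

Everything derives from one seed: the same configuration always produces the
same cohort.

:func:`run_study` runs the full method comparison on such a cohort: the
multi-time-point (MTP) reference fit per kidney-cycle, Hänscheid and Madsen
estimates from each scan day separately, the consistent cycle-1 half-life
estimate for cycles >= 2, and paired comparison records against the MTP
dose.  Because dose = TIA x S with a single S-value, percentage differences
in dose and in TIA are identical, so the same comparison records serve both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .comparison import ComparisonRecord, MethodSummary, make_comparison, summarize_method
from .estimators import (
    DoseRecord,
    PopulationHalfLife,
    SValueConfig,
    consistent_teff_tia,
    hanscheid_tia,
    madsen_tia,
    tia_to_dose,
)
from .exceptions import ConfigError, InsufficientDataError, NonPhysicalKineticsError
from .kinetics import LN2, MonoExpFit, TimeActivitySample, fit_monoexponential, tia_mtp
from .quantification import CalibrationConfig

__all__ = [
    "CohortConfig",
    "VirtualKidneyCycle",
    "StudyResult",
    "sample_cohort",
    "run_study",
    "scan_day_of",
]

#: Scan-day classification windows (hours): day 0 <= 24 h, day 4 in [72, 120],
#: day 7 >= 144.  The day-4 window doubles as the day-3-to-5 window used by
#: the consistent-half-life method.
DAY0_MAX_H = 24.0
DAY4_WINDOW_H = (72.0, 120.0)
DAY7_MIN_H = 144.0


def scan_day_of(t_h: float) -> int | None:
    """Classify a scan time into the nominal day-0/4/7 slot (None if neither)."""
    if t_h <= DAY0_MAX_H:
        return 0
    if DAY4_WINDOW_H[0] <= t_h <= DAY4_WINDOW_H[1]:
        return 4
    if t_h >= DAY7_MIN_H:
        return 7
    return None


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the virtual cohort.

    Parameters
    ----------
    n_patients : int
        Number of virtual patients.
    cycles_per_patient : int
        Therapy cycles per patient (standard course: 4).
    pop_teff_mean_h, pop_teff_sd_h : float
        Mean and SD (hours) of the population effective half-life.
    teff_truncation_h : tuple
        Lower/upper truncation (hours) of the half-life distribution.
    within_patient_teff_cv : float
        CV of the mean-one lognormal inter-cycle half-life perturbation.
    kidney_correlation : float
        Correlation between left and right kidney half-lives, in [-1, 1].
    a0_mean_MBq, a0_sd_MBq : float
        Mean/SD of the per-kidney-cycle time-zero activity (MBq).
    noise_cv : float
        CV of the mean-one lognormal multiplicative measurement noise.
    day0_hour, day4_hour, day7_hour : float
        Nominal scan times (hours post-administration).
    day4_jitter_window_h : tuple or None
        When set, the day-4 scan time is drawn uniformly from this window
        (emulating day-3-to-5 scheduling variation) instead of ``day4_hour``.
    missing_rates : tuple of 3 floats
        Independent probability that the day-0/4/7 scan of a patient-cycle
        is missing (both kidneys miss it together, as in practice).
    seed : int
        Seed of the single random generator driving everything.
    """

    n_patients: int = 150
    cycles_per_patient: int = 4
    pop_teff_mean_h: float = 56.0
    pop_teff_sd_h: float = 13.0
    teff_truncation_h: tuple[float, float] = (25.0, 110.0)
    within_patient_teff_cv: float = 0.08
    kidney_correlation: float = 0.8
    a0_mean_MBq: float = 100.0
    a0_sd_MBq: float = 20.0
    noise_cv: float = 0.06
    day0_hour: float = 4.0
    day4_hour: float = 96.0
    day7_hour: float = 168.0
    day4_jitter_window_h: tuple[float, float] | None = None
    missing_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.teff_truncation_h
        if not (0 < lo < hi):
            raise ConfigError("teff truncation bounds must be positive and ordered")
        if self.n_patients < 1 or self.cycles_per_patient < 1:
            raise ConfigError("n_patients and cycles_per_patient must be >= 1")
        if self.pop_teff_sd_h < 0 or self.within_patient_teff_cv < 0 or self.noise_cv < 0:
            raise ConfigError("SDs and CVs must be >= 0")
        if not (-1.0 <= self.kidney_correlation <= 1.0):
            raise ConfigError("kidney_correlation must be in [-1, 1]")
        if any(not (0.0 <= m <= 1.0) for m in self.missing_rates):
            raise ConfigError("missing_rates must be probabilities")
        if self.day4_jitter_window_h is not None:
            jlo, jhi = self.day4_jitter_window_h
            if not (0 < jlo <= jhi):
                raise ConfigError("day4 jitter window must be positive and ordered")


@dataclass(frozen=True)
class VirtualKidneyCycle:
    """Ground truth and measurements for one kidney in one therapy cycle."""

    patient_id: str
    cycle: int
    kidney: str
    true_teff_h: float
    true_a0_MBq: float
    true_tia_MBq_h: float
    true_dose_Gy: float
    samples: tuple[TimeActivitySample, ...]


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal factor(s) with the given CV."""
    if cv == 0.0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _truncated_bivariate_teff(rng: np.random.Generator, cfg: CohortConfig) -> tuple[float, float]:
    """Correlated (left, right) half-lives from the truncated bivariate Normal.

    Rejection sampling: redraw the pair until both components fall inside the
    truncation interval.  With the default bounds at -2.4 / +4.2 population
    SDs the acceptance rate is ~98%, so this terminates immediately in
    practice while keeping the generator stream deterministic.
    """
    lo, hi = cfg.teff_truncation_h
    rho = cfg.kidney_correlation
    for _ in range(100_000):
        z1, z2 = rng.standard_normal(2)
        zr = rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2
        left = cfg.pop_teff_mean_h + cfg.pop_teff_sd_h * z1
        right = cfg.pop_teff_mean_h + cfg.pop_teff_sd_h * zr
        if lo <= left <= hi and lo <= right <= hi:
            return left, right
    raise ConfigError("truncated half-life sampling failed; check truncation bounds")


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(100_000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise ConfigError("could not draw a positive activity; check a0 parameters")


def sample_cohort(
    cfg: CohortConfig, s_value: SValueConfig | None = None
) -> list[VirtualKidneyCycle]:
    """Draw a full virtual cohort.

    Returns one :class:`VirtualKidneyCycle` per (patient, cycle, kidney),
    carrying the latent truth (half-life, A0, TIA, dose under ``s_value``)
    and the noisy scheduled measurements.  Fixing ``cfg.seed`` fixes the
    output exactly.
    """
    s_value = s_value or SValueConfig()
    rng = np.random.default_rng(cfg.seed)
    out: list[VirtualKidneyCycle] = []
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:04d}"
        teff_patient = dict(zip(("left", "right"), _truncated_bivariate_teff(rng, cfg)))
        for cycle in range(1, cfg.cycles_per_patient + 1):
            # scan schedule shared by both kidneys of this patient-cycle
            if cfg.day4_jitter_window_h is not None:
                day4_t = rng.uniform(*cfg.day4_jitter_window_h)
            else:
                day4_t = cfg.day4_hour
            times = [cfg.day0_hour, day4_t, cfg.day7_hour]
            present = [rng.random() >= m for m in cfg.missing_rates]
            for kidney in ("left", "right"):
                teff = teff_patient[kidney] * float(
                    _lognormal_factor(rng, cfg.within_patient_teff_cv)
                )
                a0 = _positive_normal(rng, cfg.a0_mean_MBq, cfg.a0_sd_MBq)
                lam = LN2 / teff
                tia = a0 / lam
                samples = []
                for t, keep in zip(times, present):
                    noise = float(_lognormal_factor(rng, cfg.noise_cv))
                    if not keep:
                        continue  # noise drawn regardless, keeping streams aligned
                    samples.append(
                        TimeActivitySample(
                            patient_id=pid,
                            cycle=cycle,
                            kidney=kidney,
                            t_h=float(t),
                            activity_MBq=a0 * math.exp(-lam * t) * noise,
                        )
                    )
                out.append(
                    VirtualKidneyCycle(
                        patient_id=pid,
                        cycle=cycle,
                        kidney=kidney,
                        true_teff_h=teff,
                        true_a0_MBq=a0,
                        true_tia_MBq_h=tia,
                        true_dose_Gy=tia * s_value.s_Gy_per_MBq_h,
                        samples=tuple(samples),
                    )
                )
    return out


@dataclass
class StudyResult:
    """Everything the method-comparison study produces.

    ``stp_doses`` and ``comparisons`` are keyed by ``(method, scan_day)``;
    the consistent-half-life method uses scan day 4 (its day-3-to-5 scan).
    Because the S-value is a common factor, each comparison's percentage
    differences apply equally to doses and TIAs.
    """

    cycles: list[VirtualKidneyCycle]
    fits: dict[tuple[str, int, str], MonoExpFit]
    mtp_doses: dict[tuple[str, int, str], DoseRecord]
    stp_doses: dict[tuple[str, int], list[DoseRecord]]
    comparisons: dict[tuple[str, int], list[ComparisonRecord]]
    exclusions: list[dict]

    def summary(self, method: str, scan_day: int) -> MethodSummary:
        return summarize_method(self.comparisons[(method, scan_day)])

    @property
    def mean_fitted_teff_h(self) -> float:
        return float(np.mean([f.teff_h for f in self.fits.values()]))


def run_study(
    cfg: CohortConfig,
    calibration: CalibrationConfig | None = None,
    s_value: SValueConfig | None = None,
    tp_eff: PopulationHalfLife | None = None,
) -> StudyResult:
    """Simulate a cohort and compare all dosimetry methods on it.

    Per kidney-cycle: the MTP reference dose from fitting every available
    sample; Hänscheid and Madsen doses from each single scan day separately;
    and, for cycles >= 2, the consistent-half-life dose from the
    day-3-to-5 scan decay-corrected with that kidney's cycle-1 fitted
    half-life.  Kidney-cycles with fewer than two usable samples are
    excluded from the MTP reference (and hence from all comparisons) and
    logged in ``exclusions`` with a reason code.

    ``calibration`` is accepted for signature completeness: the simulated
    measurements are already activities in MBq, so the VOI-count conversion
    is bypassed; it applies when real count data are fed through
    :mod:`stpdosim.io` instead.
    """
    s_value = s_value or SValueConfig()
    tp_eff = tp_eff or PopulationHalfLife()
    cycles = sample_cohort(cfg, s_value=s_value)

    fits: dict[tuple[str, int, str], MonoExpFit] = {}
    mtp_doses: dict[tuple[str, int, str], DoseRecord] = {}
    stp_doses: dict[tuple[str, int], list[DoseRecord]] = {}
    comparisons: dict[tuple[str, int], list[ComparisonRecord]] = {}
    exclusions: list[dict] = []

    def _exclude(kc: VirtualKidneyCycle, reason: str) -> None:
        exclusions.append(
            {"patient_id": kc.patient_id, "cycle": kc.cycle, "kidney": kc.kidney,
             "reason": reason}
        )

    # pass 1: MTP reference fits
    for kc in cycles:
        key = (kc.patient_id, kc.cycle, kc.kidney)
        try:
            fit = fit_monoexponential(list(kc.samples))
        except InsufficientDataError:
            _exclude(kc, "insufficient_time_points")
            continue
        except NonPhysicalKineticsError:
            _exclude(kc, "non_physical_kinetics")
            continue
        fits[key] = fit
        mtp_doses[key] = tia_to_dose(
            tia_mtp(fit), s_value,
            patient_id=kc.patient_id, cycle=kc.cycle, kidney=kc.kidney,
        )

    # pass 2: single-time-point estimates vs the MTP reference
    for kc in cycles:
        key = (kc.patient_id, kc.cycle, kc.kidney)
        if key not in mtp_doses:
            continue
        mtp_dose = mtp_doses[key].dose_Gy
        for s in kc.samples:
            day = scan_day_of(s.t_h)
            if day is None:
                continue
            for method, tia in (
                ("hanscheid", hanscheid_tia(s.activity_MBq, s.t_h)),
                ("madsen", madsen_tia(s.activity_MBq, s.t_h, tp_eff)),
            ):
                rec = tia_to_dose(
                    tia, s_value,
                    patient_id=kc.patient_id, cycle=kc.cycle, kidney=kc.kidney,
                )
                stp_doses.setdefault((method, day), []).append(rec)
                comparisons.setdefault((method, day), []).append(
                    make_comparison(
                        patient_id=kc.patient_id, cycle=kc.cycle, kidney=kc.kidney,
                        method=method, stp_value=rec.dose_Gy, mtp_value=mtp_dose,
                    )
                )
            if day == 4 and kc.cycle >= 2:
                c1key = (kc.patient_id, 1, kc.kidney)
                if c1key not in fits:
                    _exclude(kc, "no_cycle1_fit_for_consistent_teff")
                    continue
                tia = consistent_teff_tia(s.activity_MBq, s.t_h, fits[c1key])
                rec = tia_to_dose(
                    tia, s_value,
                    patient_id=kc.patient_id, cycle=kc.cycle, kidney=kc.kidney,
                )
                stp_doses.setdefault(("consistent_teff", 4), []).append(rec)
                comparisons.setdefault(("consistent_teff", 4), []).append(
                    make_comparison(
                        patient_id=kc.patient_id, cycle=kc.cycle, kidney=kc.kidney,
                        method="consistent_teff", stp_value=rec.dose_Gy,
                        mtp_value=mtp_dose,
                    )
                )

    return StudyResult(
        cycles=cycles,
        fits=fits,
        mtp_doses=mtp_doses,
        stp_doses=stp_doses,
        comparisons=comparisons,
        exclusions=exclusions,
    )
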
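"""Dose-estimation methods for post-therapy kidney dosimetry.

Four routes from activity measurements to a time-integrated activity (TIA),
all assuming mono-exponential washout ``A(t) = A0 * exp(-lambda t)``:

* **MTP reference** — fit all available time points, integrate the fit
  (see :mod:`stpdosim.kinetics`).
* **Hänscheid approximation** — a single scan at time ``T_sc``:
  ``TIA = 2 * T_sc * A(T_sc) / ln 2``.  Exact when ``T_sc`` equals the true
  effective half-life; never overestimates a mono-exponential TIA by more
  than the factor ``2 / (e ln 2) ~ 1.0615`` (attained at
  ``T_sc = T_eff / ln 2``).
* **Madsen approximation** — a single scan plus a population effective
  half-life ``T_p``: ``TIA = T_p * A(T_sc) * 2^(T_sc/T_p) / ln 2``.  Exact
  when the patient's half-life equals ``T_p``; reduces to Hänscheid when
  ``T_p = T_sc``.
* **Consistent cycle-1 half-life** — the patient's own half-life fitted in
  cycle 1 plays the role of the population value for later cycles:
  decay-correct a single day-3-to-5 scan back to t=0 with the cycle-1
  ``T_eff`` and integrate.

TIA converts to absorbed dose through a single effective kidney self-dose
S-value (Gy per MBq*h); cross-organ dose is neglected, which cancels from
every relative comparison.  Cumulative dose per kidney is tracked against
the conventional 23 Gy kidney tolerance limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import AggregationError, ConfigError, ScheduleWarning
from .kinetics import LN2, METHODS, MonoExpFit, TiaResult

__all__ = [
    "SValueConfig",
    "PopulationHalfLife",
    "DoseRecord",
    "hanscheid_tia",
    "madsen_tia",
    "consistent_teff_tia",
    "tia_to_dose",
    "cumulative_dose",
    "check_cycle1_schedule",
    "HANSCHEID_MAX_RATIO",
    "DOSE_LIMIT_GY",
]

#: Conventional cumulative kidney absorbed-dose limit (Gy).
DOSE_LIMIT_GY = 23.0

#: Supremum of Hänscheid-TIA / true-TIA over scan times, 2/(e ln 2).
HANSCHEID_MAX_RATIO = 2.0 / (math.e * LN2)


@dataclass(frozen=True)
class SValueConfig:
    """Kidney self-dose S-value: absorbed dose per unit TIA, Gy/(MBq*h).

    The default 3.5e-4 Gy/(MBq*h) is an effective whole-kidney self-dose
    coefficient of the order of the ICRP reference-adult kidney value for
    Lu-177; it scales every dose identically, so relative method comparisons
    are independent of it.
    """

    s_Gy_per_MBq_h: float = 3.5e-4

    def __post_init__(self) -> None:
        if self.s_Gy_per_MBq_h <= 0:
            raise ConfigError("S-value must be > 0")


@dataclass(frozen=True)
class PopulationHalfLife:
    """Population effective half-life (hours) for the Madsen approximation."""

    tp_eff_h: float = 56.0

    def __post_init__(self) -> None:
        if self.tp_eff_h <= 0:
            raise ConfigError("population effective half-life must be > 0 h")


@dataclass(frozen=True)
class DoseRecord:
    """Absorbed dose of one kidney in one cycle, with method provenance."""

    patient_id: str
    cycle: int
    kidney: str
    method: str
    dose_Gy: float
    tia: TiaResult

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.dose_Gy < 0:
            raise ValueError("dose_Gy must be >= 0")


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise ValueError(f"{name} must be > 0, got {value}")


def hanscheid_tia(a_tsc_MBq: float, t_sc_h: float) -> TiaResult:
    """Hänscheid single-scan TIA: ``2 * t_sc * A(t_sc) / ln 2`` (MBq*h)."""
    _check_positive(a_tsc_MBq=a_tsc_MBq, t_sc_h=t_sc_h)
    return TiaResult(
        tia_MBq_h=2.0 * t_sc_h * a_tsc_MBq / LN2,
        method="hanscheid",
        t_sc_h=t_sc_h,
    )


def madsen_tia(
    a_tsc_MBq: float, t_sc_h: float, pop: PopulationHalfLife
) -> TiaResult:
    """Madsen single-scan TIA with a population half-life.

    ``TIA = T_p * A(t_sc) * 2^(t_sc / T_p) / ln 2`` (MBq*h).
    """
    _check_positive(a_tsc_MBq=a_tsc_MBq, t_sc_h=t_sc_h)
    tp = pop.tp_eff_h
    return TiaResult(
        tia_MBq_h=tp * a_tsc_MBq * 2.0 ** (t_sc_h / tp) / LN2,
        method="madsen",
        t_sc_h=t_sc_h,
    )


def consistent_teff_tia(
    a_tsc_MBq: float, t_sc_h: float, cycle1_fit: MonoExpFit
) -> TiaResult:
    """Single-scan TIA assuming the cycle-1 effective half-life still holds.

    The scan activity is decay-corrected to t=0 with the cycle-1 half-life
    (``A0_est = A(t_sc) * 2^(t_sc / T_eff,1)``) and integrated
    (``TIA = A0_est * T_eff,1 / ln 2``).  Algebraically identical to the
    Madsen approximation with ``T_p = T_eff,1``.
    """
    _check_positive(a_tsc_MBq=a_tsc_MBq, t_sc_h=t_sc_h)
    teff1 = cycle1_fit.teff_h
    a0_est = a_tsc_MBq * 2.0 ** (t_sc_h / teff1)
    return TiaResult(
        tia_MBq_h=a0_est * teff1 / LN2,
        method="consistent_teff",
        t_sc_h=t_sc_h,
    )


def check_cycle1_schedule(cycle1_fit_times_h: list[float]) -> bool:
    """Check the cycle-1 imaging schedule backing a consistent-T_eff estimate.

    The half-life fitted in cycle 1 is only trustworthy if the TAC was
    sampled both early and late: first scan within 24 h of administration and
    last scan at 96 h or later.  Violations warn (:class:`ScheduleWarning`)
    rather than raise, to accommodate occasional scheduling variations.

    Returns True when the schedule satisfies both constraints.
    """
    if len(cycle1_fit_times_h) < 2:
        raise ValueError("need at least two cycle-1 scan times")
    ok = min(cycle1_fit_times_h) <= 24.0 and max(cycle1_fit_times_h) >= 96.0
    if not ok:
        warnings.warn(
            f"cycle-1 scan times {sorted(cycle1_fit_times_h)} h do not span "
            "the recommended window (first <= 24 h, last >= 96 h); the fitted "
            "half-life may be unreliable",
            ScheduleWarning,
            stacklevel=2,
        )
    return ok


def tia_to_dose(
    tia: TiaResult,
    s: SValueConfig,
    *,
    patient_id: str = "",
    cycle: int = 1,
    kidney: str = "left",
) -> DoseRecord:
    """Convert a TIA to an absorbed-dose record: ``dose = TIA * S``."""
    return DoseRecord(
        patient_id=patient_id,
        cycle=cycle,
        kidney=kidney,
        method=tia.method,
        dose_Gy=tia.tia_MBq_h * s.s_Gy_per_MBq_h,
        tia=tia,
    )


def cumulative_dose(
    records: list[DoseRecord], limit_Gy: float = DOSE_LIMIT_GY
) -> tuple[float, bool]:
    """Sum per-cycle doses of one kidney and flag the cumulative limit.

    Returns ``(total_Gy, exceeds_limit)`` where the flag is True iff the
    total exceeds ``limit_Gy`` (default 23 Gy).  An empty list gives
    ``(0.0, False)``.

    Raises
    ------
    AggregationError
        Records mix patients or kidneys.
    """
    if not records:
        return 0.0, False
    keys = {(r.patient_id, r.kidney) for r in records}
    if len(keys) > 1:
        raise AggregationError(
            f"cumulative dose requires one patient and kidney, got {sorted(keys)}"
        )
    total = sum(r.dose_Gy for r in records)
    return total, total > limit_Gy
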
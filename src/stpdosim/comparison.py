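"""Paired agreement statistics between single- and multi-time-point dosimetry.

Two percentage-difference conventions are in play and must not be conflated:

* ``mtp_denominator``: ``100 * (stp - mtp) / mtp`` — the natural "error
  relative to the reference" number, used for within-threshold proportions
  and for median/IQR summaries.
* ``ba_mean_denominator``: ``100 * (stp - mtp) / ((stp + mtp) / 2)`` — the
  Bland-Altman convention (difference over pairwise mean), antisymmetric
  under swapping the two methods and bounded in (-200, 200) for positive
  values.  Used for Bland-Altman means and limits of agreement.

For a ratio r = stp/mtp the two give 100(r-1) and 200(r-1)/(r+1); they agree
near r = 1 and diverge for large disagreements (r = 0.75 -> -25% vs -28.6%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComparisonRecord",
    "MethodSummary",
    "percentage_difference",
    "make_comparison",
    "within_fraction",
    "bland_altman_summary",
    "summarize_method",
]

CONVENTIONS = ("mtp_denominator", "ba_mean_denominator")
PAIRINGS = ("per_kidney", "both_kidneys_per_cycle")


def percentage_difference(stp: float, mtp: float, convention: str) -> float:
    """Percentage difference of a single-time-point value from the reference.

    Raises
    ------
    ValueError
        Non-positive values, or an unknown convention.
    """
    if not (stp > 0) or not (mtp > 0):
        raise ValueError(f"values must be > 0, got stp={stp}, mtp={mtp}")
    if convention == "mtp_denominator":
        return 100.0 * (stp - mtp) / mtp
    if convention == "ba_mean_denominator":
        return 100.0 * (stp - mtp) / ((stp + mtp) / 2.0)
    raise ValueError(f"unknown convention {convention!r}; choose from {CONVENTIONS}")


@dataclass(frozen=True)
class ComparisonRecord:
    """One paired STP-vs-MTP result (doses or TIAs, matched kinds)."""

    patient_id: str
    cycle: int
    kidney: str
    method: str
    stp_value: float
    mtp_value: float
    pct_diff_mtp: float
    pct_diff_ba: float


def make_comparison(
    *,
    patient_id: str,
    cycle: int,
    kidney: str,
    method: str,
    stp_value: float,
    mtp_value: float,
) -> ComparisonRecord:
    """Build a :class:`ComparisonRecord`, computing both difference conventions."""
    return ComparisonRecord(
        patient_id=patient_id,
        cycle=cycle,
        kidney=kidney,
        method=method,
        stp_value=stp_value,
        mtp_value=mtp_value,
        pct_diff_mtp=percentage_difference(stp_value, mtp_value, "mtp_denominator"),
        pct_diff_ba=percentage_difference(stp_value, mtp_value, "ba_mean_denominator"),
    )


def within_fraction(
    records: list[ComparisonRecord],
    threshold_pct: float,
    pairing: str = "per_kidney",
) -> float:
    """Percentage of results within ``threshold_pct`` of the reference.

    Differences use the MTP-denominator convention.  With
    ``pairing="per_kidney"`` each record counts separately; with
    ``"both_kidneys_per_cycle"`` a patient-cycle counts only if every kidney
    recorded for it is within the threshold.
    """
    if not records:
        raise ValueError("within_fraction requires a non-empty record list")
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be > 0")
    if pairing == "per_kidney":
        ok = sum(abs(r.pct_diff_mtp) <= threshold_pct for r in records)
        return 100.0 * ok / len(records)
    if pairing == "both_kidneys_per_cycle":
        cycles: dict[tuple, bool] = {}
        for r in records:
            key = (r.patient_id, r.cycle)
            cycles[key] = cycles.get(key, True) and abs(r.pct_diff_mtp) <= threshold_pct
        return 100.0 * sum(cycles.values()) / len(cycles)
    raise ValueError(f"unknown pairing {pairing!r}; choose from {PAIRINGS}")


def bland_altman_summary(records: list[ComparisonRecord]) -> dict[str, float]:
    """Mean, SD and 95% limits of agreement of the Bland-Altman differences.

    Returns ``{"mean_pct", "sd_pct", "loa_low", "loa_high"}`` where the
    limits of agreement are ``mean +- 1.96 * SD`` (SD with ddof=1).
    """
    if len(records) < 2:
        raise ValueError("Bland-Altman summary requires >= 2 records")
    diffs = np.asarray([r.pct_diff_ba for r in records], dtype=float)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return {
        "mean_pct": mean,
        "sd_pct": sd,
        "loa_low": mean - 1.96 * sd,
        "loa_high": mean + 1.96 * sd,
    }


@dataclass(frozen=True)
class MethodSummary:
    """Per-method agreement summary (one row of a method-comparison table).

    ``within10_pct``/``within20_pct``, ``median_diff_pct``, ``iqr_pct``,
    ``sd_pct`` and ``max_abs_diff_pct`` use the MTP-denominator convention;
    ``ba_mean_pct``/``ba_1p96sd_pct`` use the Bland-Altman convention.
    """

    method: str
    n: int
    mean_dose_Gy: float
    within10_pct: float
    within20_pct: float
    max_abs_diff_pct: float
    ba_mean_pct: float
    ba_1p96sd_pct: float
    median_diff_pct: float
    iqr_pct: float
    sd_pct: float


def summarize_method(records: list[ComparisonRecord]) -> MethodSummary:
    """Summarise one method's paired comparisons into a :class:`MethodSummary`.

    ``mean_dose_Gy`` is the mean of the method's own (STP) values, so it is
    only a dose when the records compare doses.  Quantiles use linear
    interpolation so the IQR is deterministic.
    """
    if not records:
        raise ValueError("summarize_method requires a non-empty record list")
    methods = {r.method for r in records}
    if len(methods) > 1:
        raise ValueError(f"records mix methods: {sorted(methods)}")
    diffs = np.asarray([r.pct_diff_mtp for r in records], dtype=float)
    n = len(records)
    ba = (
        bland_altman_summary(records)
        if n >= 2
        else {"mean_pct": records[0].pct_diff_ba, "sd_pct": 0.0}
    )
    q25, q50, q75 = np.percentile(diffs, [25, 50, 75], method="linear")
    return MethodSummary(
        method=methods.pop(),
        n=n,
        mean_dose_Gy=float(np.mean([r.stp_value for r in records])),
        within10_pct=within_fraction(records, 10.0),
        within20_pct=within_fraction(records, 20.0),
        max_abs_diff_pct=float(np.max(np.abs(diffs))),
        ba_mean_pct=float(ba["mean_pct"]),
        ba_1p96sd_pct=1.96 * float(ba["sd_pct"]),
        median_diff_pct=float(q50),
        iqr_pct=float(q75 - q25),
        sd_pct=float(diffs.std(ddof=1)) if n >= 2 else 0.0,
    )
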
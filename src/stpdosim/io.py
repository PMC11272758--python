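"""CSV / config I/O and the reproducible pipeline driver.

Interchange is plain CSV (image handling is out of scope):

* samples table — ``patient_id, cycle, kidney, t_h, activity_MBq``
* ground-truth table — per kidney-cycle latent values from the simulator
* method summary table — one row per (method, scan day)

Configs load from YAML or JSON with sections ``cohort``, ``calibration`` and
``dosimetry`` (``s_value_Gy_per_MBq_h``, ``tp_eff_h``, ``dose_limit_Gy``).
All randomness flows from the single seed in the cohort config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortConfig, StudyResult, VirtualKidneyCycle, run_study, sample_cohort
from .comparison import MethodSummary
from .estimators import PopulationHalfLife, SValueConfig
from .exceptions import InputError
from .kinetics import KIDNEYS, TimeActivitySample
from .quantification import CalibrationConfig

__all__ = [
    "SAMPLE_COLUMNS",
    "read_samples_csv",
    "write_samples_csv",
    "write_ground_truth_csv",
    "summary_table",
    "bland_altman_table",
    "load_config",
    "RunManifest",
    "run_pipeline",
]

SAMPLE_COLUMNS = ("patient_id", "cycle", "kidney", "t_h", "activity_MBq")


def read_samples_csv(path: str | Path) -> list[TimeActivitySample]:
    """Read a samples CSV, validating schema and every row.

    Errors name the offending row (1-based data row, excluding the header).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            samples.append(
                TimeActivitySample(
                    patient_id=str(row.patient_id),
                    cycle=int(row.cycle),
                    kidney=str(row.kidney),
                    t_h=float(row.t_h),
                    activity_MBq=float(row.activity_MBq),
                )
            )
        except (ValueError, TypeError) as exc:
            raise InputError(f"{path}: row {i}: {exc}") from exc
    keys = [(s.patient_id, s.cycle, s.kidney, s.t_h) for s in samples]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise InputError(f"{path}: duplicate (patient, cycle, kidney, time) key {dup}")
    return samples


def write_samples_csv(samples: list[TimeActivitySample], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in samples], columns=SAMPLE_COLUMNS)
    _atomic_write_csv(df, path, schema="samples-v1")


def write_ground_truth_csv(cycles: list[VirtualKidneyCycle], path: str | Path) -> None:
    rows = [
        {
            "patient_id": kc.patient_id,
            "cycle": kc.cycle,
            "kidney": kc.kidney,
            "true_teff_h": kc.true_teff_h,
            "true_a0_MBq": kc.true_a0_MBq,
            "true_tia_MBq_h": kc.true_tia_MBq_h,
            "true_dose_Gy": kc.true_dose_Gy,
        }
        for kc in cycles
    ]
    _atomic_write_csv(pd.DataFrame(rows), path, schema="truth-v1")


def summary_table(result: StudyResult) -> pd.DataFrame:
    """Method-comparison table: one row per (method, scan day)."""
    rows = []
    for (method, day) in sorted(result.comparisons):
        s: MethodSummary = result.summary(method, day)
        rows.append({"method": method, "scan_day": day, **dataclasses.asdict(s)})
    df = pd.DataFrame(rows)
    return df.drop(columns=["method"]).rename(columns={"scan_day": "day"}).assign(
        method=[r["method"] for r in rows]
    )[["method", "day"] + [c for c in df.columns if c not in ("method", "scan_day")]]


def bland_altman_table(result: StudyResult, method: str, scan_day: int) -> pd.DataFrame:
    """Plot-ready Bland-Altman data: pairwise mean dose vs BA percent difference."""
    recs = result.comparisons[(method, scan_day)]
    return pd.DataFrame(
        {
            "mean_dose_Gy": [(r.stp_value + r.mtp_value) / 2 for r in recs],
            "ba_diff_pct": [r.pct_diff_ba for r in recs],
        }
    )


def load_config(path: str | Path):
    """Load ``(CohortConfig, CalibrationConfig, SValueConfig, PopulationHalfLife)``
    from a YAML or JSON file; absent sections fall back to defaults."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = raw or {}
    cohort_raw = dict(raw.get("cohort", {}))
    for key in ("teff_truncation_h", "day4_jitter_window_h", "missing_rates"):
        if key in cohort_raw and cohort_raw[key] is not None:
            cohort_raw[key] = tuple(cohort_raw[key])
    cohort = CohortConfig(**cohort_raw)
    cal = CalibrationConfig(**raw.get("calibration", {}))
    dosim = raw.get("dosimetry", {})
    s = SValueConfig(s_Gy_per_MBq_h=dosim.get("s_value_Gy_per_MBq_h", 3.5e-4))
    tp = PopulationHalfLife(tp_eff_h=dosim.get("tp_eff_h", 56.0))
    return cohort, cal, s, tp


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    seed: int
    package_version: str
    config: dict
    n_kidney_cycles: int
    n_mtp_fits: int
    n_comparisons: dict
    exclusions: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _atomic_write_csv(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write CSV atomically with a schema-version comment line."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        fh.write(f"# stpdosim {schema}\n")
        df.to_csv(fh, index=False)
    tmp.replace(path)


def run_pipeline(
    outdir: str | Path,
    cohort: CohortConfig | None = None,
    calibration: CalibrationConfig | None = None,
    s_value: SValueConfig | None = None,
    tp_eff: PopulationHalfLife | None = None,
) -> StudyResult:
    """Simulate, analyse and write all study artifacts into ``outdir``.

    Writes the samples and ground-truth CSVs, the method summary table (CSV
    and markdown), Bland-Altman plot data per method, and a JSON run
    manifest.  Identical configs (same seed) produce identical outputs.
    """
    from importlib.metadata import PackageNotFoundError, version

    cohort = cohort or CohortConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_study(cohort, calibration, s_value, tp_eff)

    write_samples_csv([s for kc in result.cycles for s in kc.samples],
                      outdir / "samples.csv")
    write_ground_truth_csv(result.cycles, outdir / "ground_truth.csv")
    table = summary_table(result)
    _atomic_write_csv(table, outdir / "method_summary.csv", schema="summary-v1")
    (outdir / "method_summary.md").write_text(table.to_markdown(index=False) + "\n")
    for (method, day) in result.comparisons:
        ba = bland_altman_table(result, method, day)
        _atomic_write_csv(ba, outdir / f"bland_altman_{method}_day{day}.csv",
                          schema="ba-v1")

    try:
        ver = version("stpdosim")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    RunManifest(
        seed=cohort.seed,
        package_version=ver,
        config=dataclasses.asdict(cohort),
        n_kidney_cycles=len(result.cycles),
        n_mtp_fits=len(result.fits),
        n_comparisons={f"{m}_day{d}": len(v) for (m, d), v in result.comparisons.items()},
        exclusions=result.exclusions,
    ).to_json(outdir / "manifest.json")
    return result
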
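"""VOI-count to kidney-activity conversion for calibrated quantitative SPECT.

A small volume of interest (VOI) placed in homogeneous kidney cortex gives a
mean count concentration; scaling it by a standard (sex-specific) kidney
volume and the camera's measured system sensitivity yields the whole-kidney
activity:

    activity [MBq] = standard_kidney_volume [cm^3] * mean_counts_per_voxel
                     / (voxel_volume [cm^3] * system_sensitivity [cts/MBq])

"Voxel size" here is the voxel *volume*, so the units close to MBq.  The
default voxel volume 0.08577 cm^3 corresponds to a 4.41 mm isotropic voxel;
the default sensitivity 9297 cts/MBq is a phantom-measured Lu-177 value for
a medium-energy-collimator SPECT protocol.

Standard kidney volumes default to single-kidney values derived from the
ICRP reference-adult kidney masses (310 g male / 275 g female, both kidneys)
at soft-tissue density 1.05 g/cm^3; they are configuration, not constants,
and should be overridden with the values your dosimetry protocol prescribes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .exceptions import ConfigError

__all__ = ["VoiStats", "CalibrationConfig", "voi_activity", "MIN_VOI_VOLUME_CM3"]

#: Smallest VOI volume (cm^3) considered representative of cortex concentration.
MIN_VOI_VOLUME_CM3 = 4.0

#: 4.41 mm isotropic voxel -> 0.441^3 cm^3.
DEFAULT_VOXEL_VOLUME_CM3 = 0.441**3

DEFAULT_SENSITIVITY_CTS_PER_MBQ = 9297.0

#: Single-kidney volumes (cm^3) from ICRP reference masses / 1.05 g/cm^3 / 2.
DEFAULT_KIDNEY_VOLUMES_CM3 = {"male": 147.6, "female": 131.0}


@dataclass(frozen=True)
class VoiStats:
    """Count statistics of one VOI.

    A warning is emitted when the VOI is smaller than
    :data:`MIN_VOI_VOLUME_CM3`, below which the mean concentration becomes
    unreliable.
    """

    mean_counts_per_voxel: float
    n_voxels: int
    voxel_volume_cm3: float

    def __post_init__(self) -> None:
        if self.mean_counts_per_voxel < 0:
            raise ValueError("mean_counts_per_voxel must be >= 0")
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be > 0")
        if self.voxel_volume_cm3 <= 0:
            raise ValueError("voxel_volume_cm3 must be > 0")
        if self.volume_cm3 < MIN_VOI_VOLUME_CM3:
            warnings.warn(
                f"VOI volume {self.volume_cm3:.2f} cm^3 is below the recommended "
                f"minimum of {MIN_VOI_VOLUME_CM3} cm^3",
                UserWarning,
                stacklevel=2,
            )

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_cm3


@dataclass(frozen=True)
class CalibrationConfig:
    """Camera calibration and standard-volume configuration."""

    system_sensitivity_cts_per_MBq: float = DEFAULT_SENSITIVITY_CTS_PER_MBQ
    standard_kidney_volume_cm3: dict = field(
        default_factory=lambda: dict(DEFAULT_KIDNEY_VOLUMES_CM3)
    )
    voxel_volume_cm3: float = DEFAULT_VOXEL_VOLUME_CM3

    def __post_init__(self) -> None:
        if self.system_sensitivity_cts_per_MBq <= 0:
            raise ConfigError("system sensitivity must be > 0 cts/MBq")
        if self.voxel_volume_cm3 <= 0:
            raise ConfigError("voxel volume must be > 0 cm^3")
        for sex, vol in self.standard_kidney_volume_cm3.items():
            if vol <= 0:
                raise ConfigError(f"standard kidney volume for {sex!r} must be > 0")


def voi_activity(voi: VoiStats, cal: CalibrationConfig, sex: str) -> float:
    """Kidney activity in MBq from VOI count statistics.

    Linear in the mean count concentration and in the standard volume;
    inversely proportional to voxel volume and system sensitivity.

    Raises
    ------
    ConfigError
        ``sex`` has no entry in ``cal.standard_kidney_volume_cm3``.
    """
    try:
        volume = cal.standard_kidney_volume_cm3[sex]
    except KeyError:
        raise ConfigError(
            f"no standard kidney volume configured for sex {sex!r}; "
            f"known: {sorted(cal.standard_kidney_volume_cm3)}"
        ) from None
    return (
        volume
        * voi.mean_counts_per_voxel
        / (voi.voxel_volume_cm3 * cal.system_sensitivity_cts_per_MBq)
    )
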
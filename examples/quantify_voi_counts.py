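"""Kidney activity from VOI count statistics of a calibrated SPECT.

A small cortical VOI gives a mean count concentration; the standard
(sex-specific) kidney volume and the camera sensitivity convert it to
whole-kidney activity in MBq.
"""

from stpdosim import CalibrationConfig, VoiStats, voi_activity

cal = CalibrationConfig()  # 9297 cts/MBq, 4.41 mm voxels, ICRP-derived volumes
voi = VoiStats(mean_counts_per_voxel=40.0, n_voxels=100, voxel_volume_cm3=0.08577)

print(f"VOI: {voi.n_voxels} voxels, {voi.volume_cm3:.1f} cm^3, "
      f"{voi.mean_counts_per_voxel:.0f} cts/voxel")
for sex in ("male", "female"):
    a = voi_activity(voi, cal, sex)
    vol = cal.standard_kidney_volume_cm3[sex]
    print(f"{sex:6s}: standard kidney volume {vol:.1f} cm^3 -> {a:.2f} MBq")
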
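# Methods

## Kinetic model and reference dosimetry

All dosimetry in `stpdosim` rests on mono-exponential washout of kidney
activity, `A(t) = A0 exp(-λt)`, valid for the post-therapy imaging window
(hours to ~1 week) of [177Lu]Lu-DOTA-TATE. Uptake-phase and bi-exponential
kinetics are out of scope: by the first scan (a few hours post-infusion)
kidney uptake is complete, and the data the methods consume (2–3 scans per
cycle) cannot constrain a second component. The time-integrated activity is
the closed form `TIA = A0/λ`; the package also carries an adaptive-quadrature
oracle (`tia_numeric_oracle`) used in testing to confirm the closed form to
1e-6 relative, with the integration horizon required to be ≥ 20 effective
half-lives so the truncated tail is below ~1e-6 of the total.

**Fitting.** The reference (multi-time-point, MTP) fit is unweighted
nonlinear least squares on the *linear* activity scale, initialised from the
log-linear ordinary regression; with exactly two points the closed-form
interpolant is used (zero residual). Linear-scale residuals weight the
high-count early scans more heavily, which is the natural weighting when the
dominant error is multiplicative on roughly count-limited data; a log-scale
fit would weight all scans equally. This choice matters only in noise: both
fits agree exactly on noise-free data. Fits implying non-decreasing activity
(λ ≤ 0) are rejected as errors rather than clamped, because every downstream
TIA formula assumes washout. Optimiser tolerances are 1e-10 on parameters
and cost; with the deterministic initialiser the pipeline is bit-reproducible
run to run.

**Units.** Time in hours, activity in MBq, TIA in MBq·h (exposed also as
MBq·s via ×3600), S-values in Gy/(MBq·h), dose in Gy.

## Quantification

Activity enters either directly in MBq or as VOI count statistics converted
by `activity = standard_kidney_volume × mean_counts_per_voxel /
(voxel_volume × system_sensitivity)`. "Voxel size" is interpreted as voxel
*volume* (cm³), which is what makes the units close to MBq; the default
0.08577 cm³ corresponds to a 4.41 mm isotropic voxel. Default sensitivity is
9297 cts/MBq (a phantom-measured Lu-177 value for a medium-energy-collimator
protocol). Standard kidney volumes are configuration, not constants; the
documented defaults (147.6 / 131.0 cm³ per kidney, male/female) derive from
ICRP reference-adult kidney masses (310 / 275 g, both kidneys) at
1.05 g/cm³. VOIs smaller than 4 cm³ trigger a warning: below that, a
cortical VOI stops being representative of organ concentration. Partial
volume, attenuation and scatter corrections are upstream of this package.

## Single-time-point estimators

Hänscheid (`2·T_sc·A(T_sc)/ln 2`), Madsen with a population half-life
(default 56 h), and the consistent cycle-1 half-life method (decay-correct a
single day-3–5 scan with the patient's own cycle-1 `T_eff`, then integrate).
The consistent method takes the scan time from the sample itself — never
assumes exactly 96 h — and checks the cycle-1 schedule (first scan ≤ 24 h,
last ≥ 96 h); violations warn rather than fail, since clinical schedules
vary. Dose conversion uses a single effective kidney self-dose S-value
(default 3.5e-4 Gy/(MBq·h), chosen so a ~100 MBq, ~56 h kidney receives
~2.8 Gy per cycle, the typical clinical scale); cross-organ dose is
neglected — it is immaterial to every relative comparison because a common
S-value cancels from percentage differences. Cumulative dose per kidney is
flagged against the 23 Gy limit.

## Agreement statistics

Two percentage-difference conventions are implemented and deliberately kept
apart: the MTP-denominator difference `100(stp−mtp)/mtp` (within-threshold
proportions, median/IQR, SD, max) and the Bland-Altman mean-denominator
difference `100(stp−mtp)/((stp+mtp)/2)` (Bland-Altman mean and
mean ± 1.96 SD limits of agreement). The BA convention is antisymmetric
under swapping methods and bounded in (−200, 200); for a dose ratio 0.75 the
two give −25% vs −28.6%, so reporting one as the other misstates large
disagreements. Within-threshold proportions support two pairings: per
kidney-result, and per patient-cycle requiring *both* kidneys within the
threshold. Quantiles use linear interpolation so the IQR is deterministic.
No multiple-comparison correction is applied anywhere. SD uses ddof=1.

## The virtual cohort

The generator stands in for unavailable patient images; it emulates the
*kinetic and scheduling structure* of a PRRT dosimetry cohort, not the
image formation:

- patient-level `T_eff` ~ Normal(56 h, 13 h) truncated to [25, 110] h — the
  truncation keeps half-lives physical while preserving the stated
  mean ± SD (it shifts the mean by only ~+0.3 h);
- left/right kidney half-lives correlated at ρ = 0.8 (both kidneys share
  the patient's physiology; the value is an assumption, exposed in config,
  and only the both-kidneys pairing metric is sensitive to it);
- per-cycle multiplicative half-life variation, mean-one lognormal CV 8% —
  true inter-cycle kinetic variability is poorly known; this is a modelling
  assumption documented as such;
- `A0` ~ Normal(100, 20) MBq per kidney-cycle, truncated positive;
- scans at 4 h / 96 h / 168 h. The day-0 scan hour is genuinely uncertain
  in clinical practice (anything from ~1 to 6 h); day-0 Hänscheid results
  are extremely sensitive to it, which is why day-0 Hänscheid agreement is
  reported but not treated as a benchmark quantity. An optional uniform
  jitter window emulates day-3–5 scheduling variation, and per-time-point
  missingness (shared by both kidneys of a patient-cycle, as in practice)
  emulates missed scans;
- measurement noise: mean-one multiplicative lognormal, CV 6% — the
  repeatability scale of quantitative Lu-177 SPECT. This is the main free
  parameter governing the within-±10% proportions and is exposed in config.

Everything is drawn from a single `numpy` Generator seeded from the config;
noise draws occur for missing scans too, so missingness does not shift the
random stream of retained values.

What passing tests on this cohort do **not** show: robustness to
reconstruction artefacts, registration failure, partial-volume and scatter
effects, non-mono-exponential kinetics, or informative (non-random)
missingness — none of which the generator models.

## Study driver and problem sizes

`run_study` fits every kidney-cycle with ≥ 2 usable samples (others are
excluded and logged with a reason code), computes Hänscheid and Madsen
estimates from each scan day separately and the consistent-half-life
estimate for cycles ≥ 2, and pairs each against that kidney-cycle's own MTP
dose. Since dose = TIA × S with a common S-value, percentage differences in
dose and TIA coincide; the same comparison records serve both readings.
Note the single day-4 scan also participates in the MTP fit, as in the
clinical design the study mirrors — STP and reference are deliberately not
independent.

The default study size used by the test suite and the acceptance script is
300 patients × 4 cycles × 2 kidneys = 2400 kidney-cycles (1800
subsequent-cycle results for the consistent method), chosen so that
Monte-Carlo error on the summary statistics (≈ 0.5 percentage points on the
Bland-Altman means) is small against the tolerances being checked while the
whole run stays at a few seconds on one CPU. Sampling-only checks use larger
cohorts since generation is cheap.

## Known limitations

- One expectation is *not* met by construction: the population mean of the
  Bland-Altman difference for Hänscheid at day 7 sits near −35% under this
  cohort, whereas the commonly quoted figure of ≈ −28% equals the analytic
  ratio at `T_eff = 56 h` exactly. Averaging the concave ratio
  `2x·2^{−x}` (x = 168 h/T_eff) over a realistic half-life distribution is
  systematically more negative than evaluating it at the mean half-life.
  The corresponding check is kept at the stricter expectation and fails,
  intentionally, as a documented property of the cohort model.
- The simulator draws A0 independently across cycles; real patients have
  correlated uptake across cycles, which would tighten consistent-method
  agreement further.
- Day-0 quantities depend strongly on the assumed 4 h day-0 scan time and
  should be read qualitatively.
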
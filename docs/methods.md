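# Methods

This note documents the models, algorithms and design choices behind
`plethys`, the assumptions the synthetic-data generator makes, and the
limits of what the test suite demonstrates.

## Signal model and breath segmentation

The pressure channel of an unrestrained whole-body plethysmograph shows
each breath as a trough-to-peak excursion: a small pre-inspiratory dip
followed by the inspiratory/expiratory pressure hump. The detector
(`breath_analysis.detect_breaths`):

1. band-passes the pressure signal with a zero-phase 2nd-order Butterworth
   filter over 0.5–30 Hz (the fundamental of mouse breathing is ~2–8 Hz;
   the upper edge keeps the harmonics that carry the pulse shape so
   amplitudes are not attenuated);
2. finds inspiratory peaks with `scipy.signal.find_peaks`, requiring a
   prominence of at least 0.3 × the robust amplitude scale (95th percentile
   of |filtered signal|) and a 50 ms refractory spacing (bounding detectable
   rate at 1200 breaths/min, far above physiology);
3. takes the minimum between successive peaks as each breath's **onset**
   (the trough that begins inspiration) and reports **amplitude** as peak
   minus preceding trough on the filtered signal.

The first peak of a record has no preceding trough; its onset is
extrapolated by the median trough-to-peak delay of the other breaths and
may precede the record start (the breath began before the recording). The
interbreath interval (IBI) is onset-to-onset; the final breath's IBI is
undefined and excluded from IBI statistics. A flat signal yields an empty
breath table rather than an error; a sampling rate below Nyquist for the
filter band raises.

Detection is oracle-tested three ways: exact counts on analytic sinusoids,
exact agreement with a brute-force local-extrema scan on noise-free
synthetic traces, and ≥ 99% onset recall within ±10 ms against simulator
ground truth at default noise.

## Artifact masking and epoch selection

Movement artifacts are broadband, high-power bursts. The automated mask
compares 0.25 s mean signal power against 12 × a robust whole-trace
reference (the 20th percentile of window power — a low quantile rather than
the median so the reference stays anchored on clean breathing even when
bursts cover half the record), then dilates flags by 0.2 s to cover burst
edges. The relative reference fails only when artifacts occupy nearly the
entire record, in which case selection reports insufficient data anyway.
At the generator's default burst intensity the mask captures ≥ 95% of burst
time while flagging ≤ 5% of clean time.

Epoch selection implements the resting-data rule used for conscious
recordings: within the last `window_s` (default 600 s) of a condition
block, artifact-free runs of at least `min_segment` (default 10 s) are
accumulated latest-first until `cumulative_target` (default 60 s) of
cumulative data is reached; whole segments are taken, so a selection can
modestly exceed the target. If the target is unreachable the selection is
returned flagged `insufficient` and the affected animal × condition cell is
excluded from analysis with a logged reason. "At rest" is approximated by
the artifact mask alone — the data model has no activity sensor.

## Ventilatory metrics

Over the selected epochs: V_f = breath count / selected minutes; V_T =
mean breath amplitude × calibration factor / body mass; V_E = V_f × V_T
(an identity by construction, tested to 1e-9 relative). The calibration
factor (mL per signal unit, default 0.005) represents the known-volume
injection calibration of the chamber; a barometric temperature-corrected
formula is intentionally out of scope — the linear factor is what an
injection calibration measures directly, and chamber temperature enters
only through that factor. Breaths belong to the interval containing their
onset (half-open intervals).

## Pattern metrics

Event definitions operate on the same epoch compilation as the ventilatory
metrics, with inclusive thresholds:

- **apnea**: IBI ≥ 2 × mean IBI of the compilation;
- **sigh**: amplitude ≥ 2 × mean amplitude of the compilation.

The compilation mean includes apneic IBIs and sigh amplitudes themselves
(single-pass, no iterative re-estimation), and rates are normalised by the
selected minutes. IBIs whose endpoints fall in different selected intervals
are excluded — a gap spanning discarded artifact time is not a breathing
pause. Both callers are property-tested against exhaustive enumeration.

Two coefficient-of-variation forms are reported for IBI and amplitude:
`cv` = (SD/√n)/mean — a standard-error-over-mean instability index, the
default reported value — and the conventional `cv_sd` = SD/mean
(= cv × √n, exactly). Sample SDs use n−1.

Poincaré descriptors use the standard short-/long-term decomposition of
the IBI first-return map: SD1² = SDSD²/2 and SD2² = 2·SDNN² − SDSD²/2
(SDNN = SD of IBIs, SDSD = SD of successive differences), so
SD1² + SD2² = 2·var(IBI) holds exactly by construction; SD2² is clipped at
zero for pathologically anticorrelated series.

## Gas exchange

A flow-through chamber at steady state obeys the mass balance
F_out = F_in − V̇O2·mass/flow, so
**V̇O2 = flow × (F_cal − F_animal) / mass** (mL O2/min/g), comparing the
empty-chamber calibration segment against live breathing over time-aligned
windows — the same epoch-selection intervals used for V_E, so the
ventilatory equivalent V̇E/V̇O2 compares like with like. The gas path
(chamber washout plus inline sensor) is modelled as first-order with time
constant τ = 1.5 s; `correct_lag` inverts one stage via
u(t) = y(t) + τ·dy/dt, differentiating a 0.2 s-smoothed copy because
differentiation amplifies sensor noise (a warning fires if the added
high-frequency content exceeds 1e-3 in fraction units). Steady-state means
are insensitive to the correction; it matters for aligning transients.
A measured animal fraction above calibration beyond a small noise tolerance
raises (nonphysical); within tolerance it clips to V̇O2 = 0, and V̇E/V̇O2 is
NaN when V̇O2 = 0. Chamber flow has no default in the assay configuration —
it is an instrument property the user must supply (the simulator's own
default is 500 mL/min for a ~25 g mouse).

## Statistical designs

- **Pre/post conditions** (room air, hypercapnia): linear mixed model
  `value ~ group * cno` with a per-animal random intercept, REML via
  `statsmodels.MixedLM`. The reported term is the group × CNO interaction —
  the difference-in-differences between the groups' pre-to-post changes.
- **Post-only conditions** (hypoxia, the four rectal-temperature
  timepoints): one value per animal, so the random intercept is
  unidentifiable and the model reduces to its degenerate between-animal
  case (OLS of group means; estimate = experimental − control). Multiple
  rows per animal (pooled assays) are averaged first.
- **Sex models** add sex and its interactions and report the
  highest-order sex-conditional contrast (group × CNO × sex, or
  group × sex for post-only designs), coded male-relative-to-female.

Inference uses a **between-within t reference**: within-animal terms get
denominator df = n_animals − n_between-animal-cells (as in nlme/SAS
containment). For the balanced pre/post design this makes the interaction
test exact — it coincides with the two-sample t-test on per-animal change
scores — and it reproduces lmerTest's Satterthwaite results on balanced
data (verified against R's lme4 in the test suite). A normal (asymptotic)
reference would reject ~8% of nulls at α = 0.05 with 6+6 animals; the t
reference is calibrated (measured type-I error 4.6–5.0% over 1000 null
cohorts). Metrics are modelled on their natural scale, significance is
p < 0.05 with no multiple-testing correction, and non-convergent fits are
returned flagged rather than silently dropped. Room-air data from the
hypercapnic and hypoxic assays can be pooled with assay provenance
retained; testing an experimental cross should use only its sibling
controls.

## The simulator

`synthetic.generate_trace` builds the pressure channel as a sum of biphasic
breath pulses on a flat baseline: a raised-cosine pre-inspiratory dip
(depth 0.5 × amplitude, ≤ 0.1 s) followed by a raised-cosine hump of height
= amplitude; pulse width is min(0.7 × IBI, 0.35 s), so long pauses leave a
flat (apneic) baseline. Ground truth records each breath's onset **at the
dip minimum** — the same landmark the detector reports — and its amplitude
as the peak-minus-trough excursion, making detector scoring well-posed.

- IBIs and amplitudes are gamma-distributed (positive, right-skewed) with
  means set per schedule block by multiplicative `effect_map` modifiers and
  dispersions given as CVs.
- An apnea replaces one IBI with `apnea_scale` × the current block mean
  (default 3×, safely beyond the 2× calling threshold plus dispersion);
  a sigh scales one amplitude by `sigh_scale` (default 3×). Both occur with
  per-breath probability rate × mean IBI / 60, i.e. approximately Poisson
  in time (verified against analytic Poisson quantiles).
- Artifacts are Poisson-timed broadband Gaussian bursts (default
  0.5/min, 0.5–2 s, SD 5 signal units) with intervals recorded.
- The O2 channel integrates the chamber mass balance toward
  F_in − V̇O2·mass/flow with exact first-order stepping (τ = 1.5 s), then
  applies a second first-order stage for the sensor and adds fraction noise
  (SD 5e-5).

Defaults describe a resting adult mouse: 0.4 s mean IBI (~150 breaths/min),
IBI CV 0.15, amplitude CV 0.12, noise 5% of mean amplitude, V̇O2
0.03 mL/min/g at 25 g, 500 mL/min flow, 21% inflow O2. Breathing-variability
dispersions are free parameters of the generator, not calibrated to any
particular animal. `generate_cohort` assigns masses (normal, 25 ± 3 g),
alternating sexes, per-animal seeds from a `SeedSequence` spawn, sibling
controls with identity modifiers, a shared assay schedule (hypercapnic:
RA/CO2/RA pre, RA/CO2/RA post; hypoxic: RA pre, RA/10% O2 post — no pre-CNO
hypoxia), an empty-chamber calibration segment per animal, and rectal
temperatures at the four protocol timepoints (baseline 37.5 °C ± 0.3, plus
configurable per-timepoint group offsets). Everything is byte-reproducible
under a fixed seed.

**What the simulator does not emulate**: real waveform morphology beyond
what the detector needs (no Ti/Te sub-phase structure, no flow-derived
volumes), ECG, activity/behaviour states, baro/thermo drift, CO2
production, or the post-sigh apnea coupling sometimes seen in vivo (sighs
and apneas are drawn independently). Passing tests therefore demonstrate
correctness of the
*analysis* under the stated signal model, not robustness to every
idiosyncrasy of real recordings.

## Problem sizes and numerical choices

Test and acceptance runs use scaled problem sizes chosen as the smallest
that exercise every stage at realistic breathing statistics: 250 Hz
sampling (the default remains 1 kHz), 120–180 s blocks with the selection
window scaled proportionally (120 s window / 60 s target / 10 s segments),
cohorts of 6+6 animals for power studies and 1000 metric-level replicates
for calibration studies. Statistical calibration is measured at the metrics
level (`simulate_metric_cohort`) because the waveform stage is irrelevant
to the sampling distribution of the fitted contrasts.

Numerical conventions: block intervals and selection intervals are
half-open `[start, end)`; times are seconds from assay start; trace files
store a strictly increasing time column with a `#` key/value header;
first-order dynamics use exact exponential stepping, not Euler; the
detector's refractory tie-break keeps the more prominent peak (inherited
from `find_peaks`); cells with fewer than 3 breaths return NaN pattern
metrics and are treated as undefined.

## Known limitations

- The artifact mask is power-based and cannot distinguish vigorous
  breathing from movement if their spectra overlap strongly.
- V_T accuracy is bounded by the band-pass amplitude response (~0.3%
  attenuation at default settings) and by the linear calibration model.
- The between-within df rule is exact only for balanced designs; for
  strongly unbalanced cohorts it is approximate (as is every non-Satterthwaite
  rule).
- `fit_group_model` with one animal per group returns an estimate with an
  unreliable SE and a low-n flag rather than refusing.
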
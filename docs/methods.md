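# Methods

This note documents the models and numerical choices behind the package: how
the synthetic gait data are generated, how each pipeline stage is defined,
which decisions were genuinely open and how they were settled, and what the
simulation does and does not tell you about real recordings.

## The measurement problem

The sagittal fetlock joint angle (FJA) is the relative rotation between the
cannon (metacarpus/metatarsus) and pastern segments. Two observation
channels measure it:

- **IMU channel.** Each segment carries an orientation sensor reporting unit
  quaternions at 200 Hz in a shared global frame. The joint rotation is
  `r = conjugate(q_cannon) ⊗ q_pastern`; the sagittal angle is the twist of
  `r` about the mediolateral axis, extracted by swing–twist decomposition
  (`θ = 2·atan2(q·axis, q_w)`), wrapped to (−180°, 180°] and unwrapped
  across samples. A standing calibration window (≥ 0.5 s; default 1 s) sets
  the zero, making flexion positive and extension negative. The angle is
  invariant to any common rigid rotation of the global frame, so the shared
  reference frame only needs to be *shared*, not aligned with anatomy.
- **OMC channel.** Three markers at the carpus/tarsus, fetlock and coffin
  joint centres are filmed in the sagittal plane at 60 Hz. The angle is the
  signed planar angle between the pastern axis (fetlock→coffin) and the
  prolongation of the metacarpus axis (fetlock→carpus, reversed), with
  dorsal rotation of the pastern positive. Frames with coincident markers
  are interpolated from neighbours; more than 10% such frames rejects the
  trial. This convention differs from the zeroed IMU angle by a constant
  (the standing dorsal angle), which the alignment step removes.

## The synthetic-data generator

No public recordings exist for this measurement setup, so the study is
exercised on simulated data. The generator is first-class, tested code; its
defaults *are* the study conditions.

### Stride-cycle waveform

One FJA cycle is a sum of wrapped Gaussian bumps on the stride-phase circle
(toe-on at phase 0): flexion peaks positive, extension troughs negative,
rescaled so the peak-to-peak range equals the requested ROM exactly and
shifted so the angle at toe-on is zero. Wrapping makes the template smooth
and periodic by construction.

- **Walk** (stance fraction 0.6): two extension troughs in stance at phases
  0.2·f and 0.8·f (relative depths 0.22 and 0.34 — the late-stance,
  push-off extension is the cycle's absolute minimum) and a double flexion
  peak in swing (relative heights 0.72 and 0.72·ratio).
- **Trot** (stance fraction 0.4): a single mid-stance extension trough
  (depth 0.18) and a double flexion peak in swing (0.82 and 0.82·ratio).

`flexion_peak_ratio` (default 0.9) sets the second flexion peak relative to
the first. Morphology is verified by counting *flexion peaks* (prominent
maxima at ≥ 20% of the template maximum) and *extension peaks* (prominent
minima at ≤ 20% of the template minimum): walk → (2, 2), trot → (2, 1).
Counting by sign matters: the shallow dip inside a double flexion peak is a
mathematical local minimum but not an extension peak, and the partial
mid-stance rebound between the walk's two extension troughs is a local
maximum but not a flexion peak. No symmetric prominence rule can separate
these (the dip's prominence equals the lesser flexion peak's), so the counts
are defined on sign and prominence together.

### Limb kinematics and the two sensor streams

The *pastern global orientation* is modelled as quiet during stance (the
hoof is planted) with a smooth sin² protraction excursion (default 40°)
during swing; the cannon orientation is then defined as
`pastern − (standing offset + FJA)`, i.e. the cannon rotating over the
planted hoof absorbs the stance extension. This is anatomically faithful and
has a practical consequence: the pastern-mounted gyroscope (the analytic
time-derivative of the pastern orientation plus white noise) shows clean
low-velocity troughs during stance, which is exactly the signal the stride
segmentation relies on. The pastern's angular velocity also crosses zero
momentarily at the protraction apex mid-swing; that dip is far shorter than
the minimum stance duration and is ignored by the hysteresis detector.

A recording is: 1 s of standing (used by the calibration), `n_strides` gait
cycles entered and left through short smoothstep ramps confined to the
partial boundary strides, and 0.5 s of trailing standing. With `n_strides`
cycles the segmenter reports `n_strides` toe-on events and `n_strides − 1`
complete toe-on→toe-on strides (the boundary partials are unusable), so the
default `n_strides = 5` leaves one stride of slack over the three the ROM
summary needs. Markers ride on a two-link planar chain (fetlock→carpus
0.25 m, fetlock→coffin 0.10 m) translated at the nominal speed with a small
vertical bob.

### Noise model and study conditions

| parameter | default | what it emulates |
| --- | --- | --- |
| gyroscope noise | 2 °/s white per axis | MEMS rate noise plus band mount jitter |
| marker noise | 1 mm white per coordinate | digitisation error of 40 mm markers at 8 m |
| soft-tissue artifact | 2 mm envelope, ≤ 3 Hz | skin/marker displacement over bone, the dominant OMC error; realised as a band-limited Gaussian process with SD = amplitude/2 (≈95% of excursions inside the envelope) |
| orientation jitter | 0.3° white on the pastern quaternion | residual sensor-fusion error |
| standing dorsal angle | −10° | the OMC convention's constant offset from the zeroed IMU angle |
| walk / trot speed | 1.53 / 3.56 m/s | published sound-group means |
| stride length walk / trot | 1.8 / 2.5 m | trot published; walk chosen for a plausible ~1.2 s stride |
| planted ROM means (front/hind, walk/trot) | 57.79/60.48, 82.83/89.40° | published sound-group means, with the published between-horse SDs |
| left–right asymmetry SD (front/hind) | 0.053 / 0.069 log-scale | targets the published sound pair CVs of ~3.0% / ~3.9% |
| lameness factor | U(0.70, 0.85) at walk; reduction halved at trot | single-limb amplitude loss giving lame-pair CVs near the published 15% (walk) / 7% (trot) |

Each lame horse gets one uniformly random lame limb. The realized
lame/contralateral amplitude ratio folds in the pair's natural asymmetry, so
a lameness factor of 1 reproduces a sound pair exactly, and the planted ROM
ratio equals the realized factor to machine precision. Horse-level draws are
seeded per horse independently of gait, so walk and trot cohorts generated
from one seed describe the same animals.

**What the simulation does not contain:** stride-to-stride amplitude
variability within a limb, out-of-sagittal-plane motion, perspective and
lens distortion in the optical channel, sensor-fusion drift, hoof-impact
spikes, and surface or speed effects. Agreement numbers on simulated data
(RMSE ≈ 2°) are therefore *better* than published field values (≈ 8°);
passing tests demonstrate the pipeline's correctness and calibration, not
field-level accuracy.

## Pipeline numerics

- **Resampling** uses a not-a-knot cubic spline evaluated strictly inside
  the original time span (exact for cubic polynomials; < 1e-3° error for a
  2 Hz sine sampled at 60 Hz).
- **Filtering** is a zero-phase forward–backward 4th-order Butterworth,
  cutoff 10 Hz: the synchronisation step compares waveform timing, which a
  causal filter would bias. Zero-phase application squares the magnitude
  response (|H(50 Hz)|² = 1/(1+5⁸) ≈ 2.6e-6). The residual pass-band loss
  on the sharp trot flexion peak costs ~0.3–0.5° of recovered ROM.
- **Synchronisation** finds, in each channel, the absolute minimum between
  the first two maxima that have prominence ≥ 20% of the range, height in
  the upper half of the range, and separation ≥ 0.2 × the expected stride
  duration (estimated from the dominant spectral period when not supplied).
  The height floor keeps the walk's mid-stance rebound — prominent but
  mid-range — from competing with the flexion peaks. The optical trace is
  then shifted vertically by the difference at the synchronisation sample.
  Under the default noise the recovered lag is within ±2 samples (10 ms) at
  trot; the walk's broader extension trough localises a little worse (a few
  samples) under the low-frequency soft-tissue artifact.
- **Stride segmentation** applies hysteresis thresholding to the (10 Hz
  low-passed) gyroscope resultant: enter stance below 8% of the robust
  (98th-percentile) maximum, leave above 15%, minimum stance 80 ms. A stance
  already in progress when the record starts is discarded (its toe-on was
  never observed); a final toe-on without toe-off is kept as a stride
  boundary. All three thresholds are configuration-exposed.
- **FJROM** is |max − min| per toe-on→toe-on stride, averaged over the first
  three complete strides (more strides are ignored, matching the
  three-consecutive-strides convention).
- **Degenerate inputs** are rejected with messages naming the quantity:
  constant series (no synchronisation maxima, no swing activity), too-short
  records for stable filtering, fewer complete strides than requested.

## Statistical layer

- **Granger temporal agreement** first-differences both traces, selects the
  lag order by BIC on the bivariate autoregression, and F-tests each
  direction; the channels agree when either direction rejects at α = 0.01
  (a both-directions rule is switchable). In the pipeline the regressions
  run on the aligned traces decimated to 50 Hz: after the 10 Hz low-pass the
  200 Hz series are ~20× oversampled, a series' own 100 ms history predicts
  it to numerical precision, and the test has no power at the native rate;
  decimation by 4 is alias-free for a 10 Hz band and restores it. The
  100 ms maximum-history window is preserved by scaling `max_lag` with the
  decimation. Type-I error at α = 0.01 on white noise is nominal (checked
  against the 99% binomial envelope over 500 replicates).
- **Bland–Altman** reports bias and bias ± 1.96·SD. With repeated measures
  per subject the difference variance is decomposed by a one-way analysis
  of differences by subject: between-subject variance is estimated from the
  subject-means mean square as (MSB − MSW)/m₀ with
  m₀ = (N − Σnᵢ²/N)/(k − 1), clipped at zero, and the limits use the total
  (between + within) SD. Fewer than two subjects, or any subject with fewer
  than two pairs, falls back to the pooled estimate with a warning.
- **Three-way ANOVA** of the left–right FJROM CV uses main effects only
  (lameness, gait, limb pair), ordinary least squares, Type II sums of
  squares, and deliberately no horse-level clustering. Percent of total
  variation is SS_factor/SS_total×100; the residual share is reported as
  the remainder to 100 (with Type II on unbalanced designs the factor SS do
  not partition SS_total exactly; on balanced designs — where Type I and
  Type II coincide, which is tested — the remainder equals the residual SS
  share). A Shapiro–Wilk screen of the residuals warns (not fails) at
  α = 0.05. Lame horses contribute only the lame pair; sound horses both
  pairs. The sample (n−1) standard deviation is used in every CV.
- **Sign conventions:** agreement differences are IMU − OMC throughout.

## Known limitations

- The standing-calibration shared-frame assumption replaces the commercial
  system's hardware baseplate calibration; orientation streams are consumed
  as the sensors output them, with no fusion or drift correction.
- The synchronisation point is a single extremum; correlated low-frequency
  marker noise moves it by a few samples at walk, which is visible as a
  ~1–2° RMSE floor in the walk agreement numbers.
- The ANOVA treats CV records as independent even though each horse
  contributes up to four of them (the deliberate no-clustering choice);
  p-values inherit that simplification.
- Only sagittal kinematics are modelled or analysed.
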
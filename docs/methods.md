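# Methods

## Overview

`mmnstrat` implements a complete analysis chain for duration-oddball EEG:
from continuous or epoched multichannel recordings to mismatch-negativity
(MMN) biomarkers, single-trial low-frequency indices, data-driven patient
stratification, and clinical characterization of the derived subgroups.
This note documents the models, the numerical choices, and what the
synthetic test surface does and does not establish.

## Paradigm and data model

The stimulation model is a 1,200-trial auditory oddball: 85% standard
tones (100 ms) and 15% duration deviants (150 ms), 200 ms inter-stimulus
interval, sampled at 512 Hz on a 64-channel scalp montage (10-10
labelling) plus two mastoids and two EOG channels. Deviants are
allocated by exact count — a shuffle of a fixed label multiset — so the
1,020/180 standard/deviant split is reproduced exactly rather than in
expectation. An optional constraint enforces a minimum number of
standards between deviants; the default is an unconstrained shuffle, as
no ordering constraint is part of the paradigm definition.

Epoch windows are −100..400 ms around stimulus onset for ERP analysis
and −100..280 ms for time-frequency analysis, with a −100..0 ms baseline.

### Sample-index convention

Millisecond boundaries map to sample offsets by round-half-up
(`floor(ms·fs/1000 + 0.5)`) and windows are half-open: an epoch of
window (start, end) at onset `o` spans `[o + r(start), o + r(start) +
r(end − start))`. At 512 Hz, a (−100, 400) ms window around sample 1000
spans samples [949, 1205), i.e. 256 samples. The same convention
fixes the MMN analysis window (inclusive of the sample nearest 120 ms,
exclusive of 250 ms) and the AverageDifference summation range
(0 inclusive to 280 ms exclusive). Any fixed convention is defensible;
this one makes epoch lengths equal to `round(span·fs/1000)` and is
applied uniformly so re-segmenting or cropping never changes sample
counts by one.

## Preprocessing

The pipeline order is: mastoid re-reference → 0.01–20 Hz band-pass →
segmentation → baseline correction → regression ocular correction →
artifact screening.

* **Re-reference**: the mean of the two mastoid channels is subtracted
  samplewise from every channel. Common-mode shifts cancel exactly.
* **Band-pass**: zero-phase (forward–backward) 4th-order Butterworth.
  The 20 Hz low-pass is a direct SOS filter. A 0.01 Hz high-pass corner
  at 512 Hz is a normalized frequency of 4·10⁻⁵, where a digital
  Butterworth is numerically unstable in double precision (measured
  passband error > 20%). The high-pass is therefore realized as drift
  subtraction: the sub-corner drift is estimated by the same-order
  Butterworth low-pass applied at a decimated rate (where the corner is
  well conditioned), linearly interpolated back to the original rate,
  and subtracted. Passband gain at 10 Hz is within ±5% and a 40 Hz tone
  is attenuated below 0.2, as verified in the tests. On signals too
  short to resolve the corner at the decimated rate the drift estimate
  degenerates to the channel mean.
* **Ocular correction**: per EEG channel, ordinary least-squares
  propagation coefficients from the two EOG channels (plus intercept)
  are estimated across all epoch samples pooled, and the scaled EOG is
  subtracted (Gratton-style regression, without raw-average-subtraction
  refinements). EOG channels retain their recorded signal for
  diagnostics. Near-zero EOG variance skips the step with a warning.
* **Artifact screening** marks an epoch rejected — with reason codes,
  never modifying voltages — if any screened channel violates any rule:
  voltage gradient above 50 μV/ms between consecutive samples (compared
  as μV per inter-sample interval), absolute amplitude above 100 μV, or
  a flat stretch (peak-to-peak below 0.5 μV over a sliding run longer
  than 100 ms). Screening is epoch-level (any channel triggers) because
  per-channel repair/interpolation is out of scope; the pipeline screens
  scalp channels only, since corrected EOG channels legitimately carry
  blinks. Out-of-bounds events from segmentation carry the reason
  `bounds`.

## MMN features

Condition averaging precedes subtraction: S1 and S2 waveforms are each
averaged over surviving epochs, subtracted (S2 − S1), and the difference
is averaged over 120–250 ms at each of the 24 frontocentral sites
(AFz, AF3, AF4, Fz, F1–F6, FCz, FC1–FC6, Cz, C1–C6 — the canonical
order of every feature matrix). The 120–250 ms window is the standard
MMN latency range for duration deviants. Longitudinal change features
are follow-up minus baseline amplitude per site; negative change means a
larger (more negative) MMN at follow-up, i.e. improvement.

## Single-trial band power and AverageDifference

Surviving single trials in the −100..280 ms window are transformed with
complex Morlet wavelets, 7 cycles at each analysis frequency — a common
ERP time-frequency default balancing time and frequency resolution over
1–13 Hz — at 0.5 Hz steps spanning each band (delta 1–4 Hz, theta
4–8 Hz, alpha 7.5–13 Hz, endpoints inclusive; the printed theta/alpha
overlap at 7.5–8 Hz is kept as defined). Band power is the mean squared
magnitude over the band's analysis frequencies, in μV².

Because a 7-cycle wavelet at 1 Hz is some 11 s long — far longer than a
380 ms epoch — the transform cannot avoid a boundary rule. The epochs
are treated as zero outside their support (the plain convolution
boundary), and the transform is evaluated as an explicit per-frequency
correlation matrix over the epoch samples. This is numerically identical
(verified to ~10⁻¹¹ relative error in the tests) to zero-padding the
epoch and running `mne.time_frequency.tfr_array_morlet` with the same
wavelets, but orders of magnitude faster for thousands of short epochs.
Delta-band power estimates from such short epochs are heavily smoothed
in time and suppressed in absolute scale; they remain comparable across
trials and subjects, which is all the downstream index uses.

The **AverageDifference** index for channel *e* is

    AverageDifference_e = Σ_t ( AvgS2_e(t) − AvgS1_e(t) ),  t ∈ [0 ms, 280 ms)

where AvgS1/AvgS2 are the samplewise means of single-trial band power
over the C_S1 standard and C_S2 deviant trials. Being a sum of squared
power differences it is heavy-tailed; values on realistic data reach the
10⁵ μV²·samples scale (serialization offers a 10⁵ display scaling;
stored values are unscaled).

**Band dominance** is assessed by a paired t-test of |AverageDifference|
pooled over subjects × channels between two bands. Note that this
comparison is *not* null even with no planted deviant-response
differential: 1/f background power (and wavelet bandwidth) differs
between bands, so the spread of the index differs systematically. The
calibration null used in the tests is therefore exchangeable by
construction — two independent replicate measurements of the same band —
rather than a between-band comparison on effect-free data.

## Stratification

Feature matrices are observations × 24 channels, one of: MMN amplitude,
MMN 6-month change, or delta-band AverageDifference. Features enter
k-means **raw** (unstandardized): the channels share units and
comparable scales, and standardizing would change the cluster geometry.

* **MAD screening** (AverageDifference runs only): an observation is an
  outlier if its 24-channel sum lies more than 3 MADs from the median,
  with MAD the plain median absolute deviation (no 1.4826 consistency
  constant — the screen is a robust rank-based cut, not a normal-σ
  estimate). A zero MAD flags nothing and warns. MMN runs are not
  screened.
* **Elbow selection**: J(k) is the best-of-restarts within-cluster sum
  of squares for k = 1..10. The automated choice is the k with the
  largest second difference J(k−1) − 2J(k) + J(k+1) — the sharpest bend
  — which reproduces the visual elbow readout while remaining testable;
  the full curve is returned for manual inspection and an override.
* **k-means**: best-of-restarts Lloyd over two init families — 50
  k-means++ restarts complemented by restarts initialized at centroids
  of random partitions. The second family matters on small instances:
  the globally optimal partition is always Lloyd-stable, but its basin
  can contain no data-point pair, making it unreachable from any
  point-seeded init (observed on random 8-point instances). Empty
  clusters trigger bounded reseeding.
* **Semantic labels**: for MMN and MMN-change features, cluster 1 is the
  cluster with the more negative grand-mean feature ("Better
  functioning" — a larger MMN is more negative); for AverageDifference,
  cluster 1 has the higher grand mean ("higher AverageDifference").

The full analysis grid comprises seven runs: MMN clustering over
controls + baseline patients, controls + follow-up patients, baseline +
follow-up patients, and patient MMN change; and delta AverageDifference
clustering over the three cohort designs.

## Cluster profiling

Per-channel cluster differences use two-sample pooled-variance (Student)
t-tests — profile tables report a single pooled SD per variable pair —
flagged at p < 0.05 with no multiplicity correction (a Benjamini–
Hochberg option exists, off by default). Clinical characterization
reports per-cluster n/mean/SD with pooled t-tests for continuous
variables and Pearson chi-square (no continuity correction) for
categorical ones; variables missing for an entire cluster (PANSS in
mixed control/patient clusters) are reported N/A, as are singleton
clusters. Three-group cohort description uses one-way ANOVA across
controls / baseline patients / follow-up patients, chi-square for sex,
and two-group t-tests for patient-only measures. Tests are two-sided by
default with a one-sided switch for directional symptom hypotheses.

## Synthetic cohorts

The generator plants known structure so every stage has a ground truth:

* **Background**: 1/f-shaped Gaussian noise, default 1 μV, the minimal
  spectral structure that makes the wavelet stage meaningful.
* **Deviance response**: a rectangular pulse over the MMN window on
  deviant trials whose window mean equals the subject's per-site profile
  *exactly* before noise, so the ERP path recovers planted amplitudes
  exactly at zero noise and within 3 standard errors under noise.
* **Two-cluster effect profiles**: per-site cluster means and pooled SDs
  at the published scale for each clustering design (MMN ≈ −3.7 vs −1.5
  μV frontally with ~1 μV SD; change ≈ −0.8 vs +2.3 μV; delta
  AverageDifference ≈ +3 vs −6 in 10⁵ μV²·samples). Subject profiles
  are drawn independently per site from the cluster model.
* **Oscillations**: post-stimulus sinusoidal bursts at band carrier
  frequencies with random phase per trial; unequal standard/deviant
  amplitudes plant band-power differentials (delta-dominant by default).
* **Blinks**: a stereotyped biphasic template on VEOG propagated to
  scalp channels with fixed coefficients, making regression correction
  exactly recoverable.
* **Artifacts**: an exact-count fraction of trials is contaminated,
  cycling the three rejection rules, each constructed to violate its
  rule with a clean margin elsewhere.
* **Clinical tables**: per-cluster normal draws from configurable
  mean/SD models (defaults at the published group statistics); PANSS
  and medication are structurally missing for controls. Hidden
  ground-truth labels travel in a `true_cluster` column consumed only by
  tests — never by analysis code.

What this establishes — and does not. Passing tests show the pipeline's
operations are correct on data with the assumed statistical structure:
stationary 1/f noise, linear blink propagation, independent per-site
cluster draws, Gaussian clinical models. Real EEG adds non-stationary
artifacts, correlated topographies, volume-conduction structure, and
non-Gaussian clinical distributions; recovery rates measured here are
upper bounds on real-data performance, not estimates of it.

### A degenerate screening interaction

Resampling independent per-channel features from *post-hoc* cluster
statistics over-disperses the separation between clusters in
24-channel-sum space. For the unbalanced delta-AverageDifference design
(10 vs 26), the minority cluster's sums then lie ~10 MADs from the
pooled median — the median and MAD are anchored in the majority cluster
— so the 3-MAD screen removes the minority cluster entirely, by
construction. This is a property of the resampling model, not of the
screen: recovery invariants are therefore asserted on the six
non-degenerate designs, and the degenerate design is covered by a test
asserting the faithful screening behavior.

## Simulation sizes

Cohort-level simulations use reduced trial counts — 240 trials/subject
for end-to-end ERP runs, 160 for time-frequency runs, keeping the 85/15
ratio — and 20–50 subjects per cohort. These sizes were chosen once as
the smallest at which the planted effects operate at realistic
signal-to-noise (the MMN standard error at 240 trials is ~0.2 μV against
~2 μV cluster separation); all effect scales come from the published
tables and are never adjusted per test.

## Known limitations

* Epoch-level inputs bypass the filtering stage; the band-pass applies
  to continuous recordings only.
* No ICA, bad-channel interpolation, or reference schemes beyond the
  mastoid average.
* Delta-band absolute power from 380 ms epochs is boundary-dominated
  (see above); only relative comparisons are meaningful.
* Continuous recordings are read from EDF/BDF but written only to the
  package's plain-text container.
* Elbow automation (max second difference) can disagree with human
  readings on shallow curves; the curve itself is always serialized for
  inspection.
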
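# Methods

This note documents the models, conventions and design choices behind
`tribp`, in the spirit of a statistical-software methods appendix.  It
states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Signal model and synthetic cohorts

The generator (`tribp.synth`) emulates a laboratory acquisition
protocol: each subject contributes four stages — a rest stage, then
three identical exercise stages, each consisting of a cycling-elevated,
a recovery and a slow-breathing block.  Every block is a 2 min
unlabelled lead-in followed by a 1 min BP-labelled interval; defaults
give 30 min of signal and 10 labelled minutes per subject at 250 Hz.
Block targets are (SBP/DBP/HR) = rest 110/70/70, cycling 135/82/100,
recovery 118/74/80, slow breathing 105/68/62; these are ordinary
textbook values for young healthy adults under moderate exercise, chosen
once.  Subject heterogeneity enters as Gaussian offsets on baseline BP
(SD 8/5 mmHg), heart rate (SD 5 bpm) and the timing intercepts (SD 8 ms
for PEP₀, 12 ms for PTT₀); each labelled minute additionally jitters the
reference by SD 1.5 mmHg, mimicking cuff-reading variability.

Waveforms are rendered from parameterized templates:

* **ECG** — sum of Gaussians (P, Q, R, S, T) with the Q trough 40 ms
  before R;
* **PPG** — a systolic Gaussian lobe (σ 35 ms) plus a dicrotic lobe, on
  a piecewise-linear diastolic-decay baseline that descends into each
  pulse foot, so the foot is a crisp local minimum rather than a flat
  stretch;
* **ICG** — dZ/dt-like wave per beat: a small negative B notch, the C
  ejection peak 100 ms later, the X trough at B + LVET, and a small O
  wave.

Blood pressure couples into the waveform linearly per beat:
PEP = PEP₀ − 0.5 ms/mmHg · (SBP − 110) and
PTT = PTT₀ − 1.0 ms/mmHg · (SBP − 110) (both intervals shorten as
pressure rises — the coupling slopes must be negative), and morphology
follows suit (pulse amplitude, systolic rise time, dicrotic amplitude
and LVET all drift linearly with BP).  On top of the deterministic
coupling, slow *vasomotor wander* — per-block/minute Gaussian
perturbations of PEP (SD 1.5 ms), PTT (SD 4 ms) and amplitudes (SD 5 %),
plus small per-beat jitter — is added independently of BP.  This is the
feature that makes the cohort informative about model ordering: an
interval-only predictor sees the wander as irreducible noise, while the
fused waveform features can average over partially independent noise
sources, so richer feature sets genuinely help rather than being
declared better by fiat.

Ground-truth fiducials are measured numerically from the rendered
noise-free channels inside narrow windows around the designed landmark
times; they are therefore exact landmarks of the clean waveform by
construction, and PAT = PEP + PTT holds exactly in sample arithmetic.

The measurement-noise model adds respiratory baseline drift (0.25 Hz
sinusoid, on PPG and ICG only — the ECG front end is drift-free), 50 Hz
mains interference and white broadband noise, with channel-specific
amplitudes: ICG is the noisiest channel and PPG carries almost no
high-frequency content (its front end is band-limited), so its
powerline/broadband defaults are very small.  With the default
amplitudes the post-filtering SNR ordering is ECG ≫ ICG ≈ PPG.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: no hemodynamic physics (no
Windkessel/Moens–Korteweg model; the BP–timing link is a linear
stand-in), no motion artifacts beyond stationary broadband noise, no
arrhythmias or ectopic beats, no sensor-contact dropout, and no
nonlinear or subject-specific curvature in the BP–PTT relationship.
Accuracy numbers on this cohort characterize the pipeline's internal
consistency, not clinical performance.

## Preprocessing

Butterworth filters, applied zero-phase (forward–backward) as cascaded
second-order sections: high-pass order 5 at 0.5 Hz for PPG and ICG
(baseline drift removal), low-pass order 15 at 10 Hz for ICG and order
15 at 40 Hz for ECG; PPG receives no low-pass.  Zero-phase application
is a deliberate choice: transit-time intervals are differences of
fiducial times, and any phase delay would bias them; the cost is
non-causality, acceptable for offline analysis.  Forward–backward
filtering applies the squared magnitude, 1/(1 + (f/f_c)^{2n}), which the
test suite checks against a measured tone (at frequencies well below
Nyquist, where bilinear-transform frequency warping is negligible).
Segmentation uses half-open 10 s windows advancing 5 s within each
labelled interval — floor((T − w)/s) + 1 complete windows, i.e. 11 per
labelled minute.  The ICG voltage-to-impedance conversion
R = V_out/(A·I_peak) is provided for completeness with the calibration
constants (module gain, excitation-current amplitude) as inputs.

## Fiducial delineation

R peaks: local maxima above an adaptive threshold (half of the 95th
percentile of candidate peak heights, which separates R spikes from T
waves) with a 0.3 s refractory period.  Q: earliest minimum in the
80 ms window before R (no standard algorithm exists; this is a
convention).  PPG: valley = minimum in (R, R + 0.6 s]; peak = maximum
between consecutive valleys; dmax = maximum of the first difference
between valley and peak.  ICG: C = maximum in (R, R + 0.4 s]; B = last
local minimum in [R, C), with maximum upward curvature (second
difference) as a fallback when no notch exists — the B point is
notoriously ambiguous in real dZ/dt recordings and the fallback
guarantees totality; X = minimum in (C, C + 0.4 s].  All ties break
toward the earliest sample.  Beats are screened for plausibility
(RR ∈ [0.3, 2] s, intra-beat ordering Q < R, B < C < X,
valley < dmax < peak, PEP ∈ [0.02, 0.20] s, PAT ∈ [0.05, 0.40] s,
PTT > 0); a segment is usable with ≥ 5 valid beats.  Detector accuracy
is assessed against ground truth with a 5-sample tolerance, matching
beats by nearest R within 0.2 s and excluding beats within 1 s of the
record edges where search windows would be truncated.

## Feature inventory

Exactly 88 PPG + 66 ICG = 154 features, frozen in code
(`features.all_feature_names`) and enforced at import time
(63 + 9 + 6 + 10 and 41 + 9 + 6 + 10).  Width features are measured at
10–90 % of pulse amplitude relative to the foot amplitude, with linear
interpolation at the crossings and last-crossing semantics on the
falling limb (so a dicrotic hump above the level extends the measured
width).  Conventions, all configurable in principle but fixed as
defaults: population (1/N) variance, biased skewness and excess
kurtosis; entropies with m = 2, r = 0.2 · SD of the series; FFT of the
mean-removed, unwindowed segment; Poincaré SD1² = ½·Var(ΔIBI) and
SD2 = √(2·SDNN² − SD1²), which makes the ellipse identity
SD1² + SD2² = 2·SDNN² exact.  A beat that cannot contribute to a
feature (level never crossed, zero variance for skewness) is excluded
from that feature's average; a feature with no contributing beats is
NaN and the segment is dropped from modelling.  Statistical features are
computed per cardiac cycle and averaged, like the morphological ones;
sequential and spectral features use the whole 10 s segment.

## Modelling and evaluation

LASSO (α = 0.1) runs once on the pooled training rows per model kind,
on internally standardized features; selection and scaling never see
test rows (a leakage-canary test enforces this).  If the penalty
removes every feature, the single best-correlated feature is used, with
a warning.  The boosted models use XGBoost with n_rounds = 300,
depth = 4, learning rate 0.05, subsample 0.9 and a fixed seed — the
hyperparameters are unremarkable small-data defaults, exposed in
`ModelSpec`.  The per-subject protocol fits one model per subject per
target on stages 1–3 and predicts stage 4; subjects lacking stage-4
rows are skipped with a log entry.  The k-fold mode partitions subjects
(never segments) into seeded folds.

Metrics follow the printed-formula conventions: ME and SDE are the mean
and *population* SD of (predicted − reference); Bland–Altman limits are
mean ± 1.96 · population SD; BHS thresholds are inclusive at the
boundary (exactly 60/85/95 % is still grade A — the standard does not
state strictness, so the generous reading is taken and documented).
Pooled aggregation over all test segments is the default; a
per-subject aggregation (average of per-subject MAE/ME/SDE/PCC) is also
available via `evaluate_predictions(..., aggregate="per-subject")`,
because the two answer different questions and mixed conventions are
common in the agreement literature.

## Problem sizes and numerical notes

The reference experiment sizes used by the acceptance script are a
20-subject cohort for fiducial-recovery assessment and a 40-subject
cohort (the full protocol, 1 320 test segments) for the end-to-end
fused-model error — the cohort size the protocol was designed around.
The test suite uses a structurally identical compact plan (30 s labelled
blocks) so unit tests stay fast.  Degenerate inputs are handled
explicitly: zero noise power reports SNR = +∞ rather than dividing by
zero; constant IBI series return 0 entropies with a warning; constant
prediction or reference series report PCC as missing (NaN); flat-line
ECG yields an empty R list and the segment is rejected downstream.
Record CSVs store samples with 17 significant digits and are read back
with round-trip float parsing, so on-disk round trips are bit-exact.

## Known limitations

The B-point fallback (curvature maximum) can disagree with the notch
definition by a few samples on heavily smoothed waveforms.  The
per-subject protocol requires the test stage's BP range to be spanned
by training stages; tree ensembles do not extrapolate, so a protocol
whose held-out stage reaches unseen pressures will show a floor/ceiling
bias — visible in the generator if the stage structure is altered.
Sample-entropy estimates on ~10 inter-beat intervals are high-variance;
they are retained because the inventory calls for them, not because
they are individually reliable at this segment length.
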
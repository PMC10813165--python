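# Methods

This note documents the models, numerical choices and limitations of
`retscreen`.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## ERG decomposition

### P3 (photoreceptoral) model

The a-wave leading edge is fit with the delayed-Gaussian saturation
function of rod phototransduction,

    P3(t) = -RmP3 · (1 - exp(-E·S·(t - td)²)),   t > td;  0 otherwise,

where `E = 10^flash_energy_log` (cd·s/m², default flash 2.07 log
cd·s/m²), `S` is a sensitivity in (cd·s·m⁻²)⁻¹·s⁻² and `td` a short
transduction delay.  This is the canonical parameterisation whose
asymptote is the saturated photoreceptoral amplitude RmP3 (µV), the
quantity tracked longitudinally.  The model trace is zero at `t ≤ td`,
monotone non-increasing and bounded below by −RmP3 (property-tested).

**Fit window.**  Leading edge only: 3 ms post-flash to 1.5 ms before
the a-wave trough.  The trough is located on an 80 Hz zero-phase
low-passed copy so oscillatory-potential ripple cannot displace it, and
the 1.5 ms margin excludes the last pre-trough samples where the rising
P2 already contributes several µV and would bias RmP3 downward.

**Optimisation.**  Bounded trust-region least squares
(`scipy.optimize.least_squares`) multi-started over a delay grid
td ∈ {2,…,8} ms with a curvature-based initial `S`; bounds
RmP3 ∈ [1, 5000] µV, S ∈ [1, 10⁵], td ∈ [1, 12] ms.  With a single
flash energy, `S` and `td` are only weakly identified (strong rm–S–td
covariance); RmP3 is the reliable, reported output and the SSE is
returned alongside.  A brute-force grid oracle over the same objective
verifies in the acceptance checks that the refined fit is never worse
than an exhaustive coarse search.

**Acquisition compensation.**  Records are acquired through a causal
analogue band-pass (0.3–1000 Hz, −3 dB).  Because that response is
known, the fit compares the *band-passed model* to the data rather than
the ideal model (the filter is linear, so the P3 component matches
exactly), and the P2 pathway inverts the first-order AC-coupling
high-pass before measuring the b-wave peak — the inverse filter
integrates the record, and over a single 640 ms sweep accumulates well
under 1 µV of noise while restoring the ~6 % slow-wave amplitude lost
to coupling droop.  Both compensations are controlled by
`DecomposeConfig.acq` and can be disabled (`acq=None`) when the
hardware response is unknown.  The residual noise-free recovery error
(≈1–2 %, reported by the acceptance script) is the remaining
distortion budget: P2/OP intrusion into the fit window plus low-pass
smoothing of the leading edge.

### P2 (bipolar-cell) isolation

Subtraction of the fitted P3 from the raw record leaves the P2-OP
complex.  P2 is isolated by a zero-phase frequency-domain filter:
forward real DFT, multiplication by a real non-negative transfer with
H(0)=1 and H(46.9 Hz)=1/√2 exactly, inverse DFT.  The transition band
is a raised cosine of full width 50 Hz positioned so the −3 dB point
falls at the nominal cutoff; the oscillatory-potential band
(≈100–140 Hz) lies entirely in the stop band.  Zero phase means a
symmetric pulse keeps its centre of mass (tested), so P2 peak *time* is
not shifted; the exact transition shape of the instrument convention
behind "46.9 Hz, −3 dB" is not recoverable, so the width is exposed as
configuration.  P2 amplitude is measured baseline-to-peak (pre-stimulus
mean to post-stimulus maximum within 0–250 ms) because the negative P3
has already been removed; a flag marks peaks on the search-window
boundary.  Peak time is computed but is not a primary endpoint.

## Synthetic cohorts

### Waveform generator

Each record is `P3 + P2 + OPs + drift + noise` passed through the
acquisition band-pass, sampled over 640 ms at 4 kHz with a 20 ms
pre-stimulus segment:

* **P3**: delayed Gaussian with defaults RmP3 = 400 µV, S = 250,
  td = 4 ms — at the 2.07 log cd·s/m² flash this puts the a-wave trough
  near 15 ms, typical of a bright-flash rodent scotopic ERG.
* **P2**: unit-peak gamma kernel `(t/t*)^(n-1) e^(n-1-t/τ)` with n = 6,
  τ = 18 ms (peak at 90 ms), amplitude 600 µV.  The b-wave's generative
  shape is not constrained by theory; a gamma kernel is the standard
  descriptive form with a controllable peak time.
* **OPs**: three Gabor bursts at 110/125/135 Hz centred 24–40 ms,
  widths 4 ms, amplitudes 40/28/18 µV — in the 60–200 Hz OP band so the
  46.9 Hz low-pass removes them, and late enough that they barely touch
  the a-wave fit window (their residual effect is part of the recovery
  budget above).
* **Noise**: white Gaussian, SD 10 µV, band-passed with everything
  else; optional slow sinusoidal drift (default off).

### Cohort structure

Four groups (WT/HOM × VEH/L-DOPA), baseline plus every 5 min to 30 min.
Amplitude of subject *i* of group *g* at time *t*:

    A_igt = A_base · geno(g) · z_i · [1 + β_i·(g_g(t) − 1)] · ν_it

* `geno` = 0.75 for HOM (congenitally attenuated responses), 1 for WT.
* `z_i`: lognormal per-subject scaler, CV 0.15, drawn once and applied
  to both RmP3 and P2 — the repeated-measures structure (within-subject
  correlation exceeds between; tested).
* `g_g(t)`: group growth, a linear ramp from 1 at baseline to 1.47
  (HOM+L-DOPA), 1.25 (HOM+VEH), 1.16 (WT+L-DOPA), 1.19 (WT+VEH) at
  30 min — the group-level drug effects the analysis is meant to
  detect.  Arbitrary per-timepoint curves can be supplied.
* `β_i ~ N(1, 0.5)`: per-subject drug-response slope heterogeneity —
  animals differ in how strongly they respond.
* `ν_it`: lognormal per-record physiological jitter, CV 0.06
  (anaesthesia depth, electrode contact).

The variance split between β and ν was chosen analytically so that the
SEM of the baseline-normalised 30-min group value is ≈8 % at n = 11 for
the strongest-responding group, the spread reported for such cohorts;
trace noise alone cannot produce that spread without destroying
single-record parameter recovery, so the spread is carried by biological
heterogeneity that is part of each record's ground truth.  Consequence,
measured by the acceptance script and left visible rather than hidden:
with this calibration the within-HOM time × L-DOPA interaction
(1.47 vs 1.25) reaches significance at α = 0.01 in ≈70 % of simulated
cohorts, short of the >80 % the validation suite asks for — the
response-heterogeneity that generates realistic SEMs sits in exactly
the error stratum that tests the interaction, a structural trade-off,
not an implementation defect.  Group means themselves are recovered
without bias (checked per cohort within 2 SEM and across a 100-cohort
ensemble).

Both eyes are collapsed to one record per subject per timepoint; the
combining rule for two-eye recordings is an open question in the
emulated workflow and averaging eyes would only shrink within-subject
noise.  Ground truth (true per-record RmP3 and P2, scalers, realised
growth, jitter) is returned with every cohort.

### OCT generator

Per-subject per-layer thickness at baseline and 30 min.  Five component
layers (RNFL 32, GCIPL 70, INL 25, OPL 18, ONL 60 µm; SDs 1.5–3 µm)
with HOM offsets −2 µm (OPL) and −5 µm (ONL) (outer-retinal thinning in
the disease model), a global per-layer decrement at 30 min
(0.8–1.8 µm; anaesthesia-related thinning) and a 0.8 µm re-measurement
SD.  Total retinal thickness is derived as the sum of component layers
plus a constant 30 µm remainder (photoreceptor segments/RPE), so TRT
additivity holds exactly in every record and TRT cannot be configured
independently.

### What the generator does not emulate

No phototransduction cascade beyond the delayed-Gaussian P3, no
pharmacokinetics (growth ramps are phenomenological), no eye-to-eye
correlation, no electrode drift/artefact epochs, no OCT segmentation
errors or image-quality variation.  Passing recovery tests therefore
demonstrates correctness of the decomposition and statistics under the
stated generative assumptions, not robustness to every artefact of real
recordings.

## Statistics

**Normalisation**: 100 × value/(subject's baseline), per measure;
baseline rows become exactly 100; subjects without a usable baseline
are excluded with a warning.

**Mixed ANOVA**: classical expected-mean-squares decomposition with one
between-subjects factor (possibly a combination of columns) and time as
the within factor.  Group → subjects-within-groups error;
time/interaction → subject × time residual.  With complete
within-subject data the cell frequencies are proportional, so the
weighted SS are orthogonal and additivity (Σ SS = SS_total,
Σ df = N−1) is asserted at construction even for unbalanced group
sizes.  Subjects missing a timepoint are listwise-deleted with a
warning (the classical method; no mixed-effects ML).  No sphericity
correction by default; Greenhouse–Geisser is available as a flag.
Cross-checked against an independent implementation (pingouin) on
unbalanced fixtures, and calibrated: type-I error of the interaction
test is 4–6 % at α = 0.05 under a 2000-rep compound-symmetric null.

**Post hocs**: pairwise group contrasts at each timepoint.  The SE of a
cell-mean difference uses the mixed-model variance of one observation,
(MS_subj + (k−1)·MS_res)/k, with Satterthwaite df.  Sidak adjustment
`1−(1−p)^m` with m = number of comparisons in the call (default family:
treatment contrast within each genotype, the comparison the screening
design cares about); both the family and m are overridable since the
convention is lab-specific.

**ROUT outliers**: the published robust-regression rule reduced to a
constant (location) model: centre = median, scale = RSDR (68.27th
percentile of |residuals|, small-sample factor n/(n−1)), two-tailed
t p-values on n−1 df, Benjamini–Hochberg step-up at Q (default 1 %)
restricted to residuals beyond 2 RSDR — which guarantees an empty
report when all residuals are within 2 robust SDs.  Behaviour: a >10
robust-SD point is always flagged; false-flag rate on clean Gaussian
n = 12 vectors is under 2 %.  Applied per group per measure per
timepoint by convention; the original workflow does not state the
grouping, so this is configurable by the caller.

## ETDRS sectors

Pixel membership: `ring_inner/2 ≤ r < ring_outer/2` in physical mm
(half-open, so boundary pixels count once), quadrants split at the
45° diagonals with superior = up; nasal/temporal depend on the eye-side
flag (OD default, OS mirrored).  Means are NaN-aware; per-quadrant
coverage is reported and <50 % coverage flags the result.  The combined
outer-ring mean (valid-pixel-weighted) is the default longitudinal
measure; per-quadrant values are retained.  Ring diameters default to
the clinical 1/3/6 mm grid as applied by the instrument; a mouse-eye
scale factor can be applied to pitch and diameters jointly (membership
is scale-invariant, tested).  Verified to machine precision against a
per-pixel double-loop oracle, plus rotation and pitch-scale invariance.

## Numerical conventions

* Zero-phase filtering via real FFT; filters are linear to machine
  precision (tested) and preserve DC exactly.
* All randomness flows through `numpy.random.default_rng` seeds carried
  in the design objects; identical (design, seed) gives bit-identical
  outputs, and all table writers use stable ordering and 6-significant-
  digit floats so runs are diffable.
* Degenerate inputs: flat records raise "no measurable a-wave"; an
  all-zero P2 trace reports zero amplitude with a boundary flag;
  constant vectors yield an empty outlier report; zero-variance ANOVA
  cells produce F = 0 (zero numerator) or F = ∞ (zero denominator with
  signal) rather than NaN.

## Problem sizes in the validation suite

Recovery uses 100 noisy records; optimiser soundness 20 fixtures
against a 1575-point grid; null calibration 2000 replicate cohorts
(n = 10/group, 7 timepoints); effect recovery one full
waveform-to-ANOVA cohort (46 animals × 7 timepoints) plus a 100-cohort
amplitude-level ensemble; interaction power 500 amplitude-level
cohorts — at the measure level the decomposition's ≈1 % error is
negligible against the 6 % record jitter, so power is a property of the
generator-plus-statistics layer and is evaluated there.  ROUT rates use
2000 clean and 200 contaminated vectors; the ETDRS oracle 20 random
maps.
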
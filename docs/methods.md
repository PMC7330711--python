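# Methods

## The pipeline

`envconn` implements the standard resting-state MEG envelope-connectome
workflow starting from ROI-level source time series (the package does not
touch sensor data, head models or inverse solutions):

1. **Spectral decomposition.** Each ROI series is band-pass filtered into
   six bands — delta 1–4, theta 4–8, alpha 8–12, low beta 13–20, high beta
   20–30, gamma 30–80 Hz — with a zero-phase (forward–backward) 4th-order
   Butterworth filter, and extended to its analytic signal
   `X = x + i·H[x]` via the Hilbert transform.  Zero-phase filtering is
   used because envelope correlation depends on envelope *timing*; a
   causal filter would delay bands differently.  A transient margin of 3×
   the filter's peak pass-band group delay is excluded at each record edge
   before any windowing.  The gamma band requires `fs ≥ 200 Hz`.

2. **Orthogonalized envelope correlation (AEC-orth).**  For a pair of
   analytic signals, `Y⊥X = Im(Y·X*/|X|)` removes the component of `Y`
   instantaneously in phase with `X`, so zero-phase-lag leakage cannot
   produce spurious correlation.  The pair value is
   `(corr(|Y⊥X|, |X|) + corr(|X⊥Y|, |Y|)) / 2` — the formula is
   asymmetric, the reported quantity is undirected — computed within
   overlapping 30-s windows (stride 1/6 of the window) and aggregated as
   the **median** across windows.  Envelopes are *not* log-transformed by
   default (`log_envelopes` exists as an opt-in switch).  Samples where
   `|X|` falls below 1e−12 of its window peak are excluded from that
   window's correlation; a window with a zero-variance (or pure-roundoff,
   see below) orthogonalized envelope contributes r = 0 for that
   direction, counted in a diagnostics counter.

3. **Graph construction.**  Per band, the connectivity matrix is
   binarized by keeping exactly `floor(density · n(n−1)/2)` strongest
   off-diagonal entries (primary density 15%, sweep 5–30% in steps of 5%).
   `floor` rather than `round` is used — "retain a proportion" reads as
   at-most — and ties break deterministically by (value desc, i asc,
   j asc) so identical inputs give identical graphs on any platform.  For
   a 446-ROI cortex at 15% this keeps 14,885 edges.  NaN entries are
   never retained.

4. **Community edge counts.**  ROIs map onto the seven canonical
   resting-state networks × two hemispheres = 14 communities; retained
   edges are counted per community (14 intra), per unordered community
   pair (91 inter), plus an `unassigned_touching` bucket for edges meeting
   an unassigned ROI (e.g. sub-cortical labels absent from the network
   template).  The three groups sum exactly to the retained edge count;
   this conservation is asserted on every call.

5. **Statistics.**  Each of the 105 measures per band is compared between
   groups with the classical pooled-variance two-sample t-test, two-sided,
   `df = n₁+n₂−2`, **without** multiple-comparison correction (an opt-in
   Benjamini–Hochberg flag exists but is beyond the default analysis);
   significance is flagged at 5% and 1%.  The reported `t` is
   (HC − BD) — negative t means the patient mean is larger — and the
   opposite orientation is carried alongside as `t_bd_minus_hc` to avoid
   sign ambiguity.  `ttest_from_summary` recomputes the same statistic
   from printed (mean, SD, n) rows, which is how published demographics
   tables are checked without raw data.  Associations with clinical
   scales (BDI-II, HAMD-17, ASRM, YMRS) use Spearman rank correlation
   (average ranks for ties) restricted to the patient group.  Zero pooled
   variance and constant score vectors raise explicit errors rather than
   returning silent infinities.

## The synthetic cohort generator

No public MEG resting-state cohort with these properties exists, so the
generator *is* the study bench.  Defaults mirror the emulated study
conditions: 22 controls, 17 patients, 7-min recordings at 1000 Hz, 446
ROIs.  Tests and examples use a desk geometry — 42 ROIs (3 per community,
none unassigned), 90 s at 250 Hz, 10+10 subjects — chosen so the full test
suite completes in minutes while keeping all 105 measures per band.

Per subject and band, each ROI receives a carrier (band-pass-filtered
unit-variance white noise) multiplied by a slow positive envelope
`a(t) = softplus(gain · (√(1−κ)·e(t) + √κ·g(t)))`, where `e` and `g` are
independent low-pass (0.9 Hz cutoff, < 1 Hz) filtered standardized
Gaussian drivers and `g` is shared within a planted community — so κ is
the planted envelope-coupling fraction.  Softplus gives a smooth,
everywhere-positive modulator; `gain = 1.4` sets the modulation depth
(envelope coefficient of variation near that of strongly modulated
resting-state band power) so that strong planted coupling (κ = 0.8) maps
onto orthogonalized-AEC values above 0.3, the range reported for robust
MEG envelope coupling.  Broadband white noise is added per ROI at a
signal-to-noise variance ratio of 1, and the observation is `X = M·S`
with `M` an instantaneous mixing matrix (identity + ε on the k nearest
ROI indices, rows normalized to unit absolute sum) emulating source
leakage.  Per-subject κ is drawn around the group mean (SD `kappa_sd`,
patients multiplied by `group_multiplier`), and clinical scores follow
`intercept + slope·κ + N(0, σ)`, truncated at 0 and rounded (scale scores
are integers); observer-rated scales (HAMD-17, YMRS) are generated for
patients only.  All draws derive from a single seed; identical specs give
bit-identical cohorts.

### Scenario calibrations (fixed once)

* `desk_cohort_spec` (group detection): κ = 0.1 in controls ×3.5 in
  patients, `kappa_sd = 0.08`, ε = 0.1.  Baseline κ = 0.1 places control
  community edges at the 15%-density retention boundary, so control counts
  vary while patient counts saturate — a realistic "present vs stronger"
  contrast detectable at n = 10+10.
* `symptom_cohort_spec` (symptom recovery): κ = 0.12 ×1.5,
  `kappa_sd = 0.12`, with steep low-noise depression-score slopes, so the
  planted community's edge count varies across patients instead of
  saturating and carries the score signal.

### What the generator does and does not emulate

It reproduces the features the estimator is sensitive to: band-limited
oscillations, slow (< 1 Hz) envelope modulation with controllable
between-ROI coupling, zero-lag linear mixing, broadband noise, group
effects and score links.  It does **not** emulate 1/f background spectra,
non-stationarity beyond the slow modulators, phase coupling, realistic
inverse-operator point-spread geometry, or artifacts.  Passing tests
therefore validate the *estimation and inference machinery* against
planted truth, not the physiological interpretation of any real dataset.

## Numerical choices

* Window bookkeeping is 0-based, half-open, a pure function of
  (n_samples, fs, scheme); `count = floor((n − w)/s) + 1`.
* The all-pairs connectivity kernel runs in float32 per window (the
  per-window correlations agree with the float64 pair path to ~1e-4,
  far below estimation error); the final median and matrix are float64
  and exactly symmetric with a NaN diagonal.
* `Im(X·conj(X))` is not exactly zero in floating point; an orthogonalized
  envelope whose peak is below 1e−10 (1e−5 in the float32 kernel) of the
  reference peak is treated as identically zero — this implements the
  "identical signals give r = 0" convention robustly.
* Proportional thresholding raises if the requested edge count exceeds the
  number of finite entries rather than retaining NaNs.
* Subject seeds derive from the cohort seed via `SeedSequence` and are
  masked below 2³¹.

## Known limitations

* **Residual leakage on directly mixed pairs.**  Pairwise
  orthogonalization cancels symmetric zero-lag mixing exactly for
  unmodulated Gaussian signals (verified by Monte Carlo), but when
  envelopes are deeply modulated a residual of order ε²·depth² survives on
  directly mixed pairs (≈ 0.09 at ε = 0.3 under the default modulation
  depth, versus ≈ 0.3 for the uncorrected estimator).  The mean |AEC-orth|
  over *all* pairs — the quantity that drives spurious edges under
  proportional thresholding — stays below 0.05.  Users comparing
  neighboring parcels should treat small orthogonalized correlations
  between spatially adjacent ROIs with caution; this mirrors the known
  behavior of pairwise leakage correction on real source data.
* Community edge counts are small integers at desk scale, so edgewise
  t-tests operate on discrete data; the null flag rate stays within the
  binomial band around 5% and p-values are approximately uniform
  (KS < 0.1), but exact uniformity is not attainable.
* The pooled t-test assumes equal group variances; with saturating counts
  the patient variance can be smaller.  This matches the cited analysis
  convention rather than a Welch correction.
* No phase-based connectivity metrics, weighted-graph statistics, or
  multiple-comparison-corrected inference are provided; they are outside
  the analysis this package reproduces.
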
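# Methods

This note documents the models, conventions, and numerical choices behind
`epiosc`, and what the synthetic cohorts do and do not emulate.

## Signal model of the synthetic cohort

Each subject is an independent set of epoched single-channel trials on
t ∈ [−200, 500] ms at 1 kHz (701 samples, both endpoints included). A
trial is the sum of three parts.

**Evoked components.** Gaussian-envelope deflections
`p · A · exp(−(t − t₀)² / 2w²)` with fixed polarity p and per-trial
latency jitter t₀ ~ N(μ, σ_jitter). Component names carry their canonical
windows (M100: 40–100 ms, M150: 100–150, M250: 150–250, M500: 250–500;
the EEG-like N1/P1/N2/P3 share the same ranges). The default jitter SD is
5 ms — small against the component windows — so components remain
phase-locked and survive trial averaging essentially undiminished.

**Induced bursts.** Amplitude-modulated sinusoids
`A · exp(−(t − t₀)²/2σ²) · cos(2πf(t − t₀) + φ)` with the carrier phase φ
drawn uniformly per trial. σ = duration/4, so the stated duration spans
±2 envelope SDs. Random phase makes the burst cancel in the trial average
(residual ~ 1/√n) while per-trial spectral analysis retains it; setting
`phase_locked=True` fixes φ = 0 to model stimulus-locked oscillatory
content. Band bounds are enforced: beta 15–29 Hz, NBG 30–100 Hz, BBG
100–250 Hz.

**Background noise.** 1/f^α noise (α = 1 by default) made by spectrally
shaping white Gaussian noise (each positive-frequency bin multiplied by
f^(−α/2), DC zeroed) and rescaling to a target RMS. Epochs are generated
directly — the analysis consumes epochs, and with 4 s inter-stimulus
intervals consecutive epochs are effectively independent; a continuous
mode exists only to exercise the epoching operation.

Group effects are multiplicative amplitude ratios and additive latency
shifts applied to the patient group's specs before synthesis; the
effective specs are retained per subject, so ground truth is exact.
Per-subject random streams are spawned from the cohort seed with
`numpy.random.SeedSequence`, giving bitwise reproducibility and subject
independence. Amplitudes are arbitrary units throughout: no physical
scale (tesla/volt) or empirical SNR is asserted.

What the generator does **not** emulate: between-subject variability of
effect sizes (all subjects of a group share identical specs, so group
separations are optimistic at a given SNR), multichannel geometry and
field spread, correlated ongoing rhythms (alpha), eye/cardiac artifacts,
and non-stationary noise. Passing tests therefore validate the analysis
machinery and its calibration, not clinical effect sizes.

## Preprocessing

Filtering is per trial: DC removal, then a fourth-order Butterworth
band-pass (1–100 Hz or 100–250 Hz) and 60/120/180/240 Hz notches
(Q = 30), applied forward–backward by default. Zero-phase application
avoids latency bias in component peaks; a single-pass mode exists for
fidelity experiments. Notches at or above the band's upper edge or
Nyquist are skipped. Epoching takes [−200, 500] ms inclusive (701 samples
at 1 kHz); events whose window leaves the record are dropped with a
warning. Stimulus-artifact interpolation replaces samples strictly inside
(−10, +10) ms by the per-trial line through the endpoint samples and
records a mask that downstream statistics honour. Outlier-run rejection
excludes a run when any feature deviates strictly more than k = 3
reference SDs ("more than" is read strictly, so a run at exactly 3.0 SD
is kept); zero-spread reference features are skipped with a warning
rather than treated as infinite z-scores. Common-average referencing has
no analogue for a single virtual channel and is deliberately absent.

## Component detection

Detection operates on the trial-averaged waveform. Upper/lower envelopes
are cubic splines through the local maxima/minima (endpoint anchors
pinned to the nearest extremum's value to suppress edge sag); a waveform
with no interior extrema falls back to the endpoint line and is flagged.
Within each component window the polarity-matched extremum of the
waveform gives latency and signed amplitude; the peak counts as found
when its detection height reaches `mean(|prestim|) + 3 · SD(prestim)`.
The threshold is inclusive (≥): "set to three standard deviations" does
not state strictness, and the inclusive reading makes the boundary case
detectable. The height is read off the envelope by default or off the
waveform itself (`mode="waveform"`); the two agree at genuine peaks since
envelopes interpolate the extrema. Windowed group comparison uses 25 ms
windows stepped 12.5 ms from stimulus onset (39 windows over 0–500 ms),
subject-level window means, rank-sum tests, and BH-FDR across windows.

## Time–frequency engine

Complex Morlet wavelets with n_cycles = 5 (σ_t = n_cycles/2πf), truncated
at ±3σ_t, L2-normalized to unit energy so raw power is comparable across
frequencies; power is the squared magnitude of the convolution
(reflection-padded, FFT-based). Frequency grids are 1 Hz steps over
1–100 Hz (evoked), 1–30/30–100/100–250 Hz (induced); 100 Hz appears on
two grids and is assigned to NBG only in feature extraction. Samples
within half the truncated wavelet support of either epoch edge are
flagged invalid per frequency; statistics and feature extraction consume
only valid pixels.

Spectral flattening multiplies each bin by its frequency; it applies only
up to 100 Hz (beyond that it overcompensates and the 100–250 Hz range is
left unadjusted) and is refused on already-flattened or baseline-corrected
maps. Flattening happens before baseline correction; for the RPC ratio
the factor f cancels, so the order matters only for raw-power outputs and
the oscillation mask.

Baseline correction: `RPC[f, t] = 100 · (P[f, t] − B_f)/B_f` with B_f the
mean power over the valid −200 to 0 ms samples at f. At low frequencies
the wavelet support can swallow the whole baseline; those rows fall back
to all baseline samples and are listed in
`meta["baseline_fallback_hz"]`. Zero baseline power is an error, not a
silent zero-division.

Evoked maps transform the trial average; induced maps flatten and
baseline-correct each trial's map and then average (so per-trial
fluctuations of baseline power are absorbed before averaging). The
trial-mean uncorrected power is retained on the map, and the oscillation
criterion marks pixels whose amplitude (√power) is at least twice
("at least" read inclusively) the mean baseline amplitude at that
frequency — "background" means the baseline period, the natural reading
where no separate noise-floor estimate exists.

### A caution on RPC and the evoked/induced dissociation

RPC is invariant to rescaling of the underlying waveform. Trial-averaging
attenuates both a random-phase burst's power and the trial-independent
background by the same factor n, so the *expected* RPC of non-phase-locked
activity is the same in evoked and induced maps; what distinguishes them
is variance (the induced ridge is stable; the evoked pixel is an
exponential-tailed single realization) and raw power, where the classic
~n-fold attenuation holds and is what the test suite verifies. Peak
*frequency* read from an RPC map also carries an irreducible jitter of a
few Hz: B_f is estimated from ~3–5 independent baseline samples at gamma
frequencies, giving ~20% row-to-row fluctuation against a ~5% per-2 Hz
deterministic falloff. The estimator is unbiased, so recovery checks
average over replicate subjects; peak latency is far more stable.

## Band features

Within a band × window rectangle (default 10–500 ms, excluding the
interpolated onset), the peak is the maximum valid RPC pixel (ties break
to earliest latency, then lowest frequency); `avg_power` is the mean RPC
over valid pixels. The optional amplitude scale reports
`sqrt(max(RPC, 0)/100)` — oscillatory amplitude in units of the baseline
amplitude — under which a planted waveform-amplitude ratio between groups
is directly recoverable (power scales as amplitude squared). Min–max
normalization maps each feature to [0, 1] across participants and errors
on constant input. The 2×-background oscillation mask can optionally gate
the peak search; it is off by default since the peak definition does not
require it.

## Group statistics

Rank-sum tests use exact enumeration for pooled n ≤ 12 without ties and
the tie/continuity-corrected normal approximation otherwise. BH-FDR is
the standard step-up procedure, applied within each analysis family.
Spearman uses midranks, exact permutation p for n ≤ 9 without ties, and
the t approximation otherwise. Multiple regression is OLS with intercept
and per-coefficient t tests; rank-deficient designs raise an error naming
the collinear columns, and categorical subtype enters as a binary
indicator.

The cluster permutation test: pooled-variance t per pixel, two-sided
pixel threshold at α = 0.05, clusters of 4-connected suprathreshold
pixels (8-connectivity by option) formed separately for positive and
negative t, cluster mass = Σt, restricted to the 10–500 ms window and the
jointly valid pixels. The reference distribution is the maximum |mass|
over whole-subject label permutations (sampled with replacement from the
permutation group, observed partition included); a cluster is significant
when |mass| strictly exceeds the 99th percentile of that distribution
(the pixel-forming α and the cluster percentile are independent knobs),
and permutation p = (1 + #{null ≥ |mass|})/(n_perm + 1), so p ≥
1/(n_perm+1). Absolute (two-sided) mass is used for the criterion since
the sidedness of the percentile rule is otherwise ambiguous.

## Classification

ANOVA F-tests screen features, BH-FDR adjusts across features, selection
keeps adjusted p < 0.05, and importance is −log10(adjusted p); features
flagged as medication-associated can be excluded up front. The SVM uses
an RBF kernel with C = 10; the kernel width is the median heuristic
(γ = 1/median squared pairwise training distance), recorded per run and
overridable. Two validation regimes are reported side by side: stratified
10-fold CV, and repeated stratified 80/20 splits whose per-split test
metrics form the reported mean ± SD and the AUC pool. Min–max scaling is
refit on the training portion of each split by default (leakage-safe); a
global mode reproduces normalize-across-everyone workflows. ROC curves
come from a threshold sweep over unique scores (equivalent to the
Mann–Whitney concordance to 1e-12), AUC by trapezoid, and the operating
point maximizes Youden's J. Confusion metrics use the five textbook
ratios, with zero-denominator ratios reported as missing rather than
zero. Pooled predicted-vs-actual independence is Pearson χ² (1 df,
no continuity correction by default).

Bootstrap AUC comparison resamples both pools with replacement
(10,000 draws), records the difference of means, and reports the
two-sided `min(1, 2·min(P(Δ ≤ 0), P(Δ ≥ 0)))`. The modality comparison
fits nested logistic regressions (deviance = −2 log L), refers
Δdeviance to χ² with df = number of added features, reduces
rank-deficient designs to an independent column subset (which leaves
deviance unchanged), and falls back to a flagged ridge-penalized fit
under separation. The χ² reference is asymptotic; calibration checks use
n = 200 per replicate, where the null Δdeviance distribution is within
Kolmogorov distance ~0.06 of χ²(3).

## Problem sizes used by the test suite and acceptance script

Chosen to keep full runs at a few minutes on one CPU while leaving
comfortable statistical margins: burst-recovery means over 20–40
replicate subjects (85 trials each, amplitude SNR 5); cluster-test
calibration over 100–200 null cohorts of 15 + 15 subjects at 200
permutations on 30 × 60 maps; sensitivity over 20–50 replicates of a
planted 50% suppression in a 30–60 Hz × 50–200 ms block; amplitude-ratio
recovery over 6–20 cohorts of 20 + 20 subjects; LRT calibration over
500 replicates at n = 200; classification demos at 15–18 subjects per
group with 100–200 splits.

## Known limitations

- No between-subject effect-size variability in the generator (see
  above); synthetic classification metrics saturate faster than clinical
  ones would.
- Evoked-map RPC inherits the short-baseline variance floor described
  above; conclusions about peak frequency from single evoked maps are
  unstable by construction of the method, not by implementation.
- The cluster test assumes exchangeable subjects between groups; no
  covariate adjustment inside the permutation scheme.
- Logistic LRT p-values are asymptotic; at small n with strong base
  features the null Δdeviance is visibly oversized relative to χ².
- Single-channel only: no sensor geometry, no cross-channel envelope
  aggregation, no source modelling.
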
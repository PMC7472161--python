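# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the choices made where the design was genuinely open.

## Problem setting

A wearable EEG headset for passive BCI has few electrodes, and its
usefulness depends on where they sit. The package treats montage design as
an optimization over *hemispherically symmetric* electrode subsets of a
32-channel 10–20 reference montage (4 midline sites Fz/Cz/Pz/Oz plus 14
left–right pairs). Symmetry is imposed both for mechanical simplicity and
because interhemispheric asymmetry features (DASM, RASM) exist only for
complete pairs. An even subset size k decomposes as p pairs + m midline
channels with 2p + m = k, so the number of admissible subsets is
Σ_p C(14, p)·C(4, k − 2p): 20, 176, 924 and 3276 for k = 2, 4, 6, 8. The
search is exhaustive; a `budget` option sub-samples configurations for
exploratory runs and logs that it did.

## Preprocessing

Order: common average reference → per-channel mean (baseline) removal →
1–55 Hz 6th-order Butterworth bandpass applied forward–backward
(zero-phase; the magnitude response is effectively squared) → segmentation
into 1-s epochs with 50% overlap → rejection of blink-contaminated epochs
→ exclusion of subjects who lose more than half their epochs (a ratio of
exactly one half keeps the subject).

Notes:

- With a 55 Hz band edge, a 60 Hz mains component is attenuated by about
  12.5 dB (|H|² ≈ 0.24), not removed; 50 Hz mains lies inside the pass
  band. No notch is applied by default (an explicit design choice to
  mirror the minimal pipeline); the bandpass spec is fully configurable.
- Baseline removal is largely subsumed by the 1 Hz high-pass edge; both
  are applied because their order is cheap and harmless.
- Blink handling rejects epochs rather than cleaning them. The detector
  is a *contract* (epoch → bool): the default flags a frontal (Fp1, Fp2,
  AF3, AF4) peak-to-peak excursion above 100 µV inside any 200 ms
  sub-window with the positive-peak-before-trough shape typical of
  blinks. The published derivative-summation detector used originally can
  be plugged in without touching the pipeline. On synthetic data with
  ground-truth blink onsets, the default detector flags >90% of epochs
  fully containing a blink with <10% false positives.

## Feature battery

Per kept epoch and channel, over six sub-bands (δ 1–4, θ 4–8, α 8–13,
low-β 13–22, high-β 22–30, γ 30–50 Hz):

- **PSD**: mean of the bare |DFT|²/N periodogram over the DFT bins whose
  frequency falls in [low, high). No taper by default (a Hann option
  exists); powers are linear, not log.
- **DASM / RASM**: left − right and left / right band power per
  interhemispheric pair (linear powers; a 1e−12 epsilon guards division).
- **Hjorth parameters**: activity = var(x); mobility = σ(Δx)/σ(x);
  complexity = mobility(Δx)/mobility(x). A constant epoch returns
  (0, 0, 0) rather than NaN.
- **Shannon entropy**: natural-log entropy of a 16-bin equal-width
  amplitude histogram spanning the epoch's min–max (bin count exposed).
- **Hurst exponent**: single-scale rescaled range, log(R/S)/log(N), with
  R the range of the cumulative mean-deviation series and S the standard
  deviation; clipped to [0, 1.5]. This single-scale form is cheap and
  monotone in persistence but biased upward for short windows (white
  noise at N = 512 averages ≈ 0.53) — it is used as a *feature*, not as
  an estimator of the true Hurst parameter.
- **Lempel–Ziv (Kolmogorov-style) complexity**: the signal is binarized
  at its median and parsed into distinct phrases (1976 variant); the
  count c(n) is normalized by b(n) = n/log₂(n), so random sequences
  approach 1. A compiled (numba) parser is used when available; a pure
  Python parser is the reference implementation and both are
  cross-checked in the tests.
- **Third-order cumulant**: E[x_k·x_{k+1}·x_{k+2}] of the mean-removed
  epoch (lags (1, 2), exposed). The time-domain reading was chosen over a
  bispectral one; for symmetric distributions it vanishes in expectation,
  so it captures waveform asymmetry.
- **CSP**: one-vs-rest common spatial patterns per (band, class):
  epoch covariances are trace-normalized, averaged per side, and the
  generalized eigenproblem of (target, target + rest) is solved with a
  tiny ridge (1e−6·trace/n_ch) for rank safety. The eigenvectors of the
  largest and smallest eigenvalues are kept — 2 filters — and the feature
  is log(var(Z_p)/Σᵢ var(Z_i)). That yields 12 CSP features per class
  (2 × 6 bands) and 48 in total, which is what makes the printed battery
  sizes (632 full montage, 162 for a 6-channel/3-pair subset) come out
  exactly; a "2 filters per band" reading is the only one consistent with
  those totals.

Column count is validated against the closed-form counting rule at
extraction time (a cross-module invariant).

## Emotion evaluation

Per subject and electrode subset: features are ranked by the multi-class
Fisher ratio Σ_c n_c(μ_c − μ)² / Σ_c n_c σ_c², capped at 20 features, and
scored with a linear classifier under repeated stratified K-fold CV
(10 × 10 by default). Design choices:

- **Fold granularity is the trial.** Epochs overlap by 50% and are
  strongly autocorrelated within a trial; epoch-level folds leak. The
  guard test demonstrates the failure mode: with *shuffled* labels,
  epoch-level folds on overlapping epochs yield ≈ 0.37 accuracy (the
  classifier memorizes each trial's label majority through near-duplicate
  feature rows), while trial-level folds stay at chance. Test trials are
  labelled by majority vote over their epochs; an epoch-level mode exists
  for independent-epoch data.
- **Selection and CSP run inside folds.** CSP models and the Fisher
  ranking are refitted on each training fold. The non-CSP columns are
  label-free and therefore computed once per subject (a pure speed
  optimization with no leakage).
- **Prefix policy.** "Best achievable accuracy with ≤ 20 features" is
  under-specified. `select_features` supports a nested mode (default for
  the public operation): prefixes top-1…top-20 are compared by inner CV
  on training data and ties break toward fewer features. The exhaustive
  search (`optimize`) uses the fixed top-20 mode by default because the
  nested mode multiplies the search cost ~60× for a small accuracy
  difference; the mode is a parameter.
- **Classifiers**: linear SVM (C = 1, one-vs-one) as primary, LDA and
  decision tree as alternates. Features are standardized inside the fold
  (fit on training rows only) — the battery mixes scales across many
  orders of magnitude and the margin optimizer converges poorly
  otherwise; Fisher ranking is affine-invariant, so selection is
  unaffected.

## Attention evaluation

The behavioral index over a window of trials is CONC = (N_CT − N_IT)/N_TT
— correctly minus incorrectly discriminated *targets*, over all targets;
distractor responses do not enter. Windows slide over trials (94 trials,
50% overlap at full scale → 27 windows for 1316 trials). Per window the
battery is computed on the concatenation of the window's kept trials;
each feature's 27-point (or desk-scale 19-point) series is correlated
with the CONC series (Pearson by default, Spearman optional), and a
subject's score is the largest |r| over features; a configuration's score
is the subject mean. Blink-rejected trials leave both the behavioral
counts and the EEG concatenation, keeping the two series aligned; windows
losing every target trial become NaN and drop pairwise.

CSP needs class labels that the attention task does not define. The
default bins windows into CONC *quartiles* (4 attention levels), which
keeps the CSP block at 4 classes × 12 features and the battery size
identical to the emotion battery — the binding constraint being the
printed counts. A high/low median-split mode is available; degenerate
splits fall back gracefully (median, then omitting the CSP block with a
warning).

## Search and statistics

`optimize` evaluates every admissible subset of size k under the design's
objective (mean accuracy / mean best |r| / GCS = accuracy + |r|, computed
from subject-averaged terms), ranking deterministically: enumeration
order is pairs-first, lexicographic by montage declaration, and argmax
keeps the earliest of tied maxima. `compare_designs` runs a Friedman test
across paired per-subject metrics (χ² reported; all-tied data reported as
χ² = 0, p = 1), followed — when significant at 0.05, or directly for two
designs — by Wilcoxon signed-rank tests with Bonferroni correction, plus
a Kolmogorov–Smirnov normality screen. Consumer-headset presets are
shipped as named, user-configurable channel sets for comparison runs;
their exact channel identities are best-effort placeholders.

## Synthetic data: what a green test establishes

The generators emulate the *structure* of the two source experiments, not
their biophysics: independent per-channel 1/f Gaussian background at
10 µV RMS, band-limited Gaussian signal components (no pure sinusoids),
biphasic 100–300 µV frontal blink transients at Poisson times (10/min for
the emotion profile) with ground-truth onsets.

- **Emotion profile** (desk scale: 8 subjects, 128 Hz, 40 × 10-s trials,
  10 per quadrant; full scale 512 Hz / 60 s behind `full_scale()`): the
  four classes differ in alpha power and its lateralization at F7/F8
  (bilateral ×3, left-only ×3, right-only ×3, none) — the classic
  frontal-alpha-asymmetry valence signature, and four linearly separable
  spectral patterns.
- **Attention profile** (desk scale: 8 subjects, 400 × 0.5-s trials,
  45% targets; full scale 1316 trials): a smoothed random walk normalized
  to [0, 1] is the latent attention drift; P(correct) = 0.25 + 0.65·drift,
  and alpha power *redistributes* between Fz (∝ drift) and Pz
  (∝ 1 − drift) with coupling strength 2 — an anterior–posterior power
  shift. The redistribution (rather than co-varying power at both sites)
  is what makes the *pair* {Fz, Pz} the uniquely most informative subset:
  with identical coupling at both sites, a CSP variance-ratio between one
  planted site and any quiet reference channel tracks the drift equally
  well and single-planted configurations tie with the planted pair.
- Desk-scale attention analyses use a 40-trial/50% window (19 windows);
  the paper-scale 94-trial window applies to full-scale runs, and the
  1316-trial → 27-window identity is asserted separately.

What the generators do **not** model: volume conduction and channel
covariance (channels are independent), realistic artifact diversity
(only blinks), non-stationary background, electrode noise or impedance
drift. A green planted-recovery test therefore establishes that the
pipeline measures and ranks the information it is pointed at — not that
a particular montage is optimal for real EEG.

## Numerics and degenerate inputs

- All randomness flows through seeded `numpy` generators; eigensolvers
  and sorts are deterministic, ties break by stable order.
- Constant signals: Hjorth → (0, 0, 0); Hurst → 0; entropy → 0; RASM's
  denominator is epsilon-guarded with a warning.
- Rank-deficient covariances are ridge-stabilized
  (λ = 1e−6 · trace/n_ch) unconditionally — cheap, and a no-op at
  working precision for well-conditioned input.
- The filter+covariance pass runs in float32 (the trace-normalized
  covariances are insensitive at that precision); everything else is
  float64.

## Known limitations

- Input formats are the delimited text matrix (+ JSON sidecar) only; no
  EDF reader is bundled because no EDF library is available in the
  supported environment. The reader interface is a single function, so
  adding one is mechanical.
- The per-window attention battery recomputes features per window rather
  than incrementally; at full scale (27 windows) this is still cheap.
- The search is exhaustive by design; k = 8 at full CV on real-size data
  is days of compute — use `budget`, a reduced `CvSpec`, or the cached
  per-subject feature reuse (automatic within one process).
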
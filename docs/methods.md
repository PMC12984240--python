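# Methods

## Signal model and feature extraction

The extractor treats a recording as a real matrix of shape L × Nc
(time samples × channels). A window of 8 consecutive sample rows slides
over the time axis with unit step, giving W = L − 7 windows; signals
shorter than 8 samples are rejected. Within each window the four
center-symmetric differences `D_k = V_k − V_{9−k}` (k = 1..4, rows
1-based) are computed channel-wise, and each `D_k` is replaced by the
1-based channel indices of its values sorted in descending order. Ties
are broken toward the smaller channel index with a stable sort — the
choice is arbitrary but must be fixed, since constant signals and
quantized amplitudes produce ties routinely and downstream counts must
be reproducible bit-for-bit.

Concatenating the per-window permutations in time order yields four
integer sequences of length Nc·W. Adjacent ordered pairs are counted
into four Nc × Nc transition matrices; counting runs across window
boundaries, so each matrix totals Nc·W − 1. The feature vector is the
concatenation of the four row-major flattenings, length 4·Nc². Row-major
order is load-bearing: the symbolic decoder inverts exactly this layout
(`row = ((f−1) div Nc) mod Nc + 1`, `col = (f−1) mod Nc + 1`, f
1-based), and the outer modulo folds all four matrices onto one channel
grid, so indices f, f+Nc², f+2Nc², f+3Nc² decode identically.

Features stay raw integer counts; normalization happens once, in the
selector. Two exact invariances follow from the construction and are
enforced as property tests: invariance under `a·x + b` applied to the
whole matrix (a > 0), and the per-window permutation property of every
Nc-block of the transformed sequences.

## Segmentation and I/O

Recordings are cut into consecutive non-overlapping windows of
`seg_seconds × fs` samples (15 s at 256 Hz → 3840 rows in the odor-study
configuration); a trailing remainder is discarded rather than
zero-padded, because padding would inject artificial center-symmetric
structure. No filtering, re-referencing or artifact rejection is applied
anywhere. CSV (comma or tab, auto-detected, decimal point) and EDF/EDF+
are supported; EDF reading goes through mne, with an explicit
header-level check that all data signals share one sampling rate, since
mne would otherwise silently resample a mixed-rate file.

## Feature selection

Each sample row of the feature matrix is min-max normalized by its own
range, `x → (x − min) / (max − min + ε)` with ε = 10⁻¹² (the per-sample
orientation is deliberate and unconventional; it makes each segment's
count profile comparable regardless of its total). A diagonal NCA then
learns one weight per feature: distances are
`d_w(x_i,x_j) = Σ_r w_r² |x_ir − x_jr|`, neighbor probabilities
`p_ij ∝ exp(−d_ij)` (self excluded), and the objective is the expected
leave-one-out correct-classification count minus `λ Σ w_r²` with
λ = 1/Ns. Optimization is deterministic: all-ones initialization,
analytic gradient (verified against central differences in the tests),
L-BFGS with an iteration cap of 100. Reported weights are the squares of
the raw parameters, hence non-negative. The softmax is computed with a
per-row shift for numerical stability; a single-feature matrix
short-circuits to keeping that feature, since the L2 penalty alone would
otherwise drive its weight to zero.

Features are ordered by descending weight (ties toward the smaller
original index) and the selected count is the smallest m whose top-m
mass reaches `th × Σ w` (default th = 0.9999). The selected matrix is
materialized from the *normalized* features — the normalization step
overwrites the matrix before columns are copied — so the classifier
consumes normalized columns, while the reported indices refer to
original column positions.

## Classification

The ensemble sweeps 10 neighbor counts × 4 distances × 3 vote
weightings = 120 kNN parameterizations. Spearman distance is 1 minus the
rank correlation of feature vectors, with a constant vector's
correlation defined as 0; inverse weights use `1/(d + δ)`, δ = 10⁻¹².
All tie-breaks are fixed: distance ties to the earlier training index,
vote and mode ties to the smallest class value, accuracy ties to the
earlier outcome. Folding is stratified (scikit-learn `StratifiedKFold`)
with a seeded shuffle; each parameterization yields one pooled
out-of-fold prediction vector. Outcomes are sorted by accuracy,
majority votes over the top-3 … top-120 add 118 voted outcomes, and the
maximal-accuracy outcome among all 238 is returned.

**Known optimistic design, reproduced deliberately.** Feature selection
runs once on the full labeled dataset before cross-validation, and the
final outcome is chosen by comparing all 238 outcome vectors against the
full label vector. Both steps leak label information into the reported
best accuracy. This is the pipeline's defining evaluation protocol and
is reproduced as such, not corrected; the consequence is quantified
below under limitations. Users wanting an unbiased generalization
estimate should wrap the *entire* pipeline in an outer CV loop.

Metrics (accuracy, sensitivity, specificity, precision, F1, geometric
mean) come from the confusion matrix; binary problems use a declared
positive class, multiclass metrics are macro-averaged one-vs-rest, and
any zero-denominator ratio is reported as 0 with a warning flag.

## Symbolic explanation

Each selected feature index decodes to its (row, col) channel pair; each
channel maps to a two-letter region symbol via a look-up table. When the
table is auto-built from 10–20 labels, the lobe letter comes from the
prefix (Fp/AF/F/FC/FT → F, T/TP → T, C/CP → C, P/PO → P, O → O) and the
hemisphere from digit parity (odd → left, even → right) or a trailing
`z` (midline). This convention makes exactly 14 of the 16 symbols
reachable for a 32-channel frontal-through-occipital cap (the auditory
symbols AL/AR need dedicated electrodes); the boundary assignments
(FC/FT to frontal, CP to central, PO to parietal) are a convention and
fully overridable with a user-supplied two-column LUT file.

The symbol sequence emits row symbol then column symbol per feature
(length = 2 × selection size); the hemispheric sequence is the second
letter of each symbol. Reports contain histograms, transition matrices
over the full sequence (totals = length − 1), Shannon entropy in bits
(zero-probability terms contribute 0), and complexity ratios
entropy / log₂(alphabet size) using the *utilized* alphabet sizes —
14 for region symbols, 3 for hemispheres — which is the only
denominator consistent with the published complexity figures the tests
reproduce. Hemisphere totals quoted from sequence analyses are symbol
occurrence counts (they sum to the sequence length); cross-hemispheric
"cross-talk" is the count of consecutive L→R and R→L pairs.

## Synthetic data

The generator emulates labeled segment sets: each channel is an AR(1)
series `x_t = ρ x_{t−1} + ε_t` with stationary initialization,
ρ = 0.9, unit innovation scale, and a multiplicative gain g on a
class-specific channel subset (left-frontal F3 for one class,
right-frontal F4 for the other). The gain is the only class signal —
chosen because the extractor is invariant to global scale, so the
signal must be channel-differential to be detectable. Defaults: 8
channels at 64 Hz, 5-s segments (L = 320, W = 313, 256 features), 30
segments per class, g = 3, one master seed from which per-segment seeds
derive. AR(1) noise is analytically transparent and cheap; it does not
emulate 1/f spectra, oscillatory bands, eye-blink artifacts or volume
conduction, so passing tests demonstrate that the pipeline recovers
channel-differential amplitude structure — not that it handles
physiological EEG confounds.

## Problem sizes and determinism

The default test and demonstration scale (60 segments × 256 features,
10-fold CV, 238 outcomes) runs the full pipeline in well under a second
on one CPU; the brute-force oracle comparison uses 200 random signals
with Nc ∈ {2,3,4}, L ∈ {8..30}. All randomness flows from explicit
seeds (generator master seed, fold shuffle seed); rerunning a
configuration reproduces every JSON report byte-for-byte.

## Limitations

- **Selection leakage at small n.** With 60 samples and 256 features the
  diagonal NCA can maximize its leave-one-out objective on pure noise,
  concentrating nearly all weight mass on a few dozen chance features;
  out-of-fold kNN on those pre-selected columns then reaches ~0.9
  accuracy even when labels carry no information (measured 0.90–0.95
  across seeds on the g = 1 null configuration). This is the documented
  consequence of the select-then-cross-validate protocol above, not an
  implementation artifact; at the odor-study scale (1113 samples) the
  effect is smaller but not zero. The null-control acceptance test
  records this behavior.
- The greedy best-of-238 choice is similarly optimistic; the margin it
  adds is bounded by the spread of the 238 out-of-fold accuracies.
- The channel→symbol table for caps with FC/FT/CP/PO electrodes encodes
  a boundary convention; users with different anatomical conventions
  should supply their own LUT.
- Published-sentence statistics are reproduced from transcribed
  sentences; the upstream recordings behind them are not distributed
  with this package.
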
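# Methods

This note records the models implemented in `agndesign`, the parameter
choices that matter, and what the synthetic-data tests do and do not
demonstrate.

## Staple featurization

A 10-base template is represented by the counts of all ordered gapped
base pairs X\_mY ("staple" motifs): component (X, Y, m) counts positions
i with `seq[i] = X` and `seq[i+m+1] = Y`, read 5′→3′, for m = 0…8. This
gives 4 × 4 × 9 = 144 features, and every 10-mer contains exactly
Σ<sub>m</sub>(9 − m) = 45 staple occurrences. Design choices:

- **Feature order** is fixed as X-major, Y-minor, m innermost
  (`A_0A, A_1A, …, A_8A, A_0C, …`) and shared by models, CSV headers and
  importance tables.
- **X\_mY and Y\_mX are distinct** (the two ends of a rod-shaped cluster
  are not equivalent with respect to strand direction), giving exactly
  144 features rather than a merged 90.
- **Raw integer counts**, not frequencies: all sequences have the same
  length, so scaling would only rescale the SVM regularization path.
- Input is uppercased on read; RNA-style `U` is rejected rather than
  mapped to `T` to avoid silently accepting the wrong molecule.

A property worth recording: with the full gap range m = 0…8 the staple
map is **injective** on 10-mers — exhaustive enumeration of all 4¹⁰
sequences produces 1,048,576 distinct vectors, so no two templates share
a feature vector. The representation is "positionally independent" in
the sense that it discards absolute positions (except via the m = 8
end-to-end component), not in the sense of collapsing distinct sequences.
Truncated gap ranges do collapse sequences (with m ≤ 0, `AAAAAAAACA`
and `AAAAAAACAA` share a vector). One-hot encoding (length 4L, one
indicator per position×base) is provided as the positional baseline.

## Spectral fitting

Emission spectra are converted from wavelength to photon energy
(E = hc/λ, hc = 1239.842 eV·nm, sample order reversed so energy
ascends) and fitted to sums of k = 1…3 Gaussians with `lmfit`. No
Jacobian correction of intensities is applied on the change of variable
(raw counts are fitted against energy); a `FitConfig.apply_jacobian`
flag enables it.

- **Initialization** is deterministic: candidate centers are the local
  maxima of the Savitzky–Golay-smoothed trace (window 7, order 2),
  strongest first; the k-component fit warm-starts from the (k−1) fit
  plus one new component (nested initialization), so adding a component
  cannot worsen the optimum — if it does, the previous fit is kept.
- **Model selection**: components are added while the residual sum of
  squares drops by at least 5% (`rel_improvement`); a fit that is exact
  to machine precision stops the ladder immediately.
- **Amplitude floor**: components with height below 3 × a robust noise
  estimate (1.4826 × MAD of the fit residuals) are discarded, with a
  tiny relative term (10⁻⁹ × max intensity) to drop machine-precision
  ghosts. A flat noise trace therefore yields an empty peak set.
- **Width floor**: σ is bounded below by the coarsest energy-axis
  sampling step, preventing the optimizer from "fitting" single noise
  spikes; real emission bands (σ ≈ 0.05 eV) are far wider.
- Optimizer failure returns a `PeakSet` with the `error` field set, not
  an exception, so plate-scale batch fitting never aborts.

Brightness is peak area divided by a control emitter's area
(`normalize_brightness`), making brightnesses comparable across plates.

## Color classes and curation

Classes: Green λ<sub>p</sub> < 580 nm, gap [580, 600] (excluded — the
cluster magic number is unknown there), Red (600, 660], Far Red
(660, 800], NIR > 800 nm, Dark = no bright emission. The literature
writes strict inequalities on both sides of each boundary and never
resolves equality; the half-open convention above is this package's
choice and every boundary is configurable.

Curation labels each sequence by its **brightest bright peak** and
excludes: sequences with bright peaks in ≥ 2 classes ("multiclass"),
sequences whose brightest bright peak falls in the 580–600 nm gap
("gap"), and sequences whose strongest emission sits in the mediocre
band ("mediocre"). Every input row lands in exactly one of the labeled
set or the exclusion log. Thresholds: the bright threshold defaults to
0.2 (control-normalized area) and the mediocre band to [0.5, 1.0) × the
bright threshold. The experimental values live in unpublished analysis
details; these defaults are package choices exposed in
`CurationConfig`, and the synthetic generator emits areas well above
the bright threshold so tests do not sit on the boundary.

Two labeling conventions exist for NIR because NIR emission is recorded
on a separate instrument: by default the multiclass exclusion applies to
all classes; with `nir_overrides_training=True` any sequence with a
bright NIR peak is labeled NIR regardless of other peaks. Both are
implemented and flag-selected rather than guessing a single intent.
Design-outcome evaluation (`evaluate_design_outcome`) follows the
separate-instrument logic: visible targets are judged by the brightest
bright *visible* peak; an NIR target succeeds if any bright NIR peak
exists, and dual labels (NIR + visible class) are emitted when both are
present.

The wavelength cutoffs are supported by 1-D k-means on the pooled
λ<sub>p</sub> values. `kmeans_cutoffs` solves the 1-D problem **exactly**
by dynamic programming over the sorted values (O(k·n²) with vectorized
inner loops), removing Lloyd-iteration seed dependence; in 1-D the
optimal clusters are contiguous runs, so the DP optimum is the global
optimum and reproduces what a converged Lloyd run finds. Midpoints
between consecutive centroids are the candidate class boundaries.

## Classifier ensemble

For each of the 10 unordered class pairs, the majority class is randomly
subsampled (without replacement, minority class kept whole) to the
minority size, 10 times; one `LinearSVC` (L1 penalty, squared hinge,
dual=False, c = 0.1, the value selected in the source study) is trained
per subsample, giving 100 classifiers. Choices where the design was
open:

- **Probability calibration**: a linear SVM emits a margin, not a
  probability; the default maps the signed margin d through the logistic
  function p = 1/(1+e⁻ᵈ) — parameter-free, monotone, rank-preserving,
  and exactly complementary between the two class orientations
  (P(A|pair) + P(B|pair) = 1 to machine precision). Platt scaling (an
  inner logistic refit of margins onto labels) is available via
  `TrainingConfig.calibration = "platt"`.
- **No feature scaling** by default (counts are 0–9 and commensurate;
  L1 weights stay interpretable); `standardize=True` is available.
- **Consensus rule**: the predicted class maximizes the *minimum* of its
  four pairwise average probabilities — the same min-of-pairs score the
  design screen uses, so prediction and design rank identically. Ties
  break on the fixed class order Dark < Green < Red < FarRed < NIR and
  are flagged.
- **Cross-validation**: per pair and repeat, one balanced subsample is
  drawn, split into 10 class-stratified folds (stratification is this
  package's choice), and fold accuracies are averaged; the report gives
  mean ± sd over repeats (default 100; tests and the acceptance script
  use 3 where the quantity is far from its threshold, 100 for the
  permutation null).
- **Reproducibility**: one root seed drives subsampling, fold draws and
  solver seeds via `numpy.random.SeedSequence` spawning; models
  serialize to JSON (weights, biases, feature order, config, data
  fingerprint) and reload bit-identically.

## Feature importance

BorutaShap-style selection without the SHAP dependency: each repeat
draws a balanced subsample, appends one shuffled shadow copy of every
real column, fits a 100-tree random forest, and records every real feature's
importance and the repeat's maximum shadow importance. Attribution uses
the forest's mean-decrease-in-impurity importances; the selection
contract is attribution-agnostic (feature vs. max shadow). A feature is
selected when mean importance exceeds the mean shadow maximum; for pairs
involving NIR — whose small class size inflates subsampling variance —
features within one standard deviation of the bar are also selected.

NIS(f, c) = Σ over the four pairs (c, o) of sign(freq_c(f) − freq_o(f))
× MISA(f, pair), where freq is the class's mean per-sequence count of
the feature on the curated training set; exact frequency ties contribute
zero. This follows the published prose definition of the score; the
original's exact formula lives in unpublished supplementary notes, so
the sign-rule form here is the package's documented interpretation.

## Design screen

All 4ᴸ sequences are streamed in fixed-size blocks (default 65,536) as
integer code arrays; features, pair probabilities and the min-of-pairs
score are computed vectorized per block, and a rolling top-k buffer is
merged with each block by a stable sort, so memory is O(block + k)
regardless of L and ties break lexicographically (blocks arrive in
lexicographic order). L is guarded to ≤ 12. k defaults to 124 (one
384-well plate = 3 × 124 designs + 10 controls + 2 spare). An optional
exclude list drops (e.g.) training-library sequences from the ranking;
it is off by default. On one CPU the full 4¹⁰ screen takes ~10 s with a
100-member ensemble; training takes ~2 s on 4,000 sequences.

## Synthetic data generator

The generator emulates the statistical structure the classifier assumes:
class identity is determined by staple-motif content through a *linear*
score per class (w·counts + intercept, label = argmax), matching the
linear SVM's capacity so perfect recovery is achievable at zero label
noise. Default conditions mirror the experimental library: proportions
Dark 0.30, Green 0.08, Red 0.20, FarRed 0.38, NIR 0.04 (FarRed ≈ 10×
NIR; Green and NIR the smallest fluorescent classes), and motifs chosen
so adjacent Gs drive FarRed/NIR, C-rich motifs drive fluorescence,
mixed G/C adjacency drives Red, and motif-poor sequences stay Dark.
Sequences are drawn class-conditionally (a random positive motif of the
target class is planted into a random sequence, accepted when the class
wins the argmax uniquely); label noise flips each label to a uniform
other class with probability ε. Class quotas use largest-remainder
allocation, so achieved proportions match targets to rounding. An
`xor_stress_rules` profile with a non-linearly-separable Green/Red
distinction documents the linear model's expected failure mode.

Synthetic spectra give each non-Dark record one Gaussian peak (σ
0.04–0.06 eV) at a wavelength uniform in its class interval with area
0.5 (2.5× the bright threshold), plus white noise; Dark records are
noise-only. What passing tests therefore show: the pipeline recovers
planted linear motif rules, calibrated noise rates, and class-consistent
spectra end to end. What they do not show: performance on real
chemistry — real Ag<sub>N</sub>-DNA labels are not exactly linear in
staple counts, spectra can hold up to three overlapping peaks with
instrument-dependent noise, and the two-instrument λ<sub>p</sub>
distribution artifacts are not emulated.

## Problem sizes used in tests and the acceptance script

The synthetic study runs at n = 5,000 sequences (4,000 train / 1,000
held out), ε = 0, default imbalance — large enough that the ~40 held-out
NIR sequences make recall meaningful and achieved proportions sit within
±2% of targets. Cross-validation uses 3 repeats where the measured
accuracy is far above its threshold and the full 100 repeats for the
shuffled-label permutation null (whose mean must land within 0.5 ± 0.05).
Shadow importance uses 3 repeats of 100-tree forests per pair in
end-to-end checks and 5–10 in focused unit tests.

## Known limitations

- The model is trained on, and designs, 10-base templates only; longer
  templates would need a feature-length policy for m near L−2.
- Linear margins + logistic calibration give well-ordered but not
  empirically calibrated probabilities; treat scores as rankings.
- MDI importances are biased toward high-cardinality features in
  general; here all features are small counts on a common scale, and the
  shadow comparison is made under the identical bias.
- The exact DP k-means is quadratic in n; it is instant for the few
  thousand peak wavelengths it is meant for, not for millions of points.
- Spectral fitting assumes Gaussian bands in energy and at most three
  components, as the source instrumentation pipeline did.
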
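# Methods

`rooibosml` benchmarks machine-learning classifiers against a classical
Gaussian baseline on the task of labelling rooibos (*Aspalathus linearis*)
samples as fermented (FR) or unfermented (UFR) from six phytochemical
measurements: total phenolic content (TPC, mg GAE/g), Trolox-equivalent
antioxidant capacity (TEAC, µmol TE/g) and ferric-reducing antioxidant power
(FRAP, µmol AAE/g), each obtained from a water and a methanol extract of the
same plant sample. This note records the statistical model, the synthetic
data generator, the numerical choices, and the limitations a user should
know about before trusting a result.

## The synthetic data generator

The original 98-sample laboratory dataset is not publicly archived, so every
analysis here runs on synthetic data drawn from a per-class multivariate
Gaussian whose parameters are reconstructed from the published per-class
summary statistics:

- **Means** are the published per-class averages of all six measurements,
  taken verbatim (e.g. UFR methanol TPC 302.66 GAE/g).
- **Standard deviations** are not published; they are reconstructed from the
  published per-class min–max ranges as σ = range / 4.5, since the expected
  range of roughly 50 iid normal draws is ≈ 4.5 σ. This is an assumption,
  overridable through `GeneratorParams`.
- **Correlations.** The published pairwise table reports signed squared
  correlations (its column contains a negative entry, −0.012, so it cannot
  be a plain r²). Each within-solvent pair (TPC–TEAC, TPC–FRAP, TEAC–FRAP)
  is converted to a Pearson ρ by ρ = sign(v)·√|v|, preserving both magnitude
  and direction. Cross-solvent correlations are set to zero, matching the
  reported absence of association between the water and methanol values of
  the same assay. With these entries both assembled 6×6 correlation matrices
  are already positive semidefinite; a repair step (eigenvalue clipping at
  1e−8 followed by rescaling to unit diagonal) exists for user-supplied
  parameter sets that are not.
- **Class sizes** default to the study's 51 FR and 47 UFR samples.
- **Non-negativity.** Assay values cannot be negative. Rows containing a
  negative draw are redrawn from the same stream rather than clipped, so the
  retained distribution stays Gaussian in the bulk; under the default
  parameters the closest margin is ≈ 4 σ and redraws essentially never fire.
  A cap of 100 redraws per sample raises an error to surface pathological
  parameter sets.
- **Reproducibility.** Each class draws from `master_seed + class_offset`,
  so FR and UFR streams are independent and the whole dataset is
  bit-reproducible from `(params, seed)`.

What the generator deliberately does **not** emulate: seasonal/habitat
variation between harvests, the FR water-extract outliers visible in the
original scatter plots (a flag-free design: no outlier injection), assay
measurement error structure (triplicate averaging), and any non-Gaussian
tails. Tests passing on synthetic data therefore certify the pipeline's
correctness and the internal consistency of the published summary
statistics — not distributional claims about new laboratory data.

One consequence worth flagging: the water-extract blocks have nearly equal
class means but different spreads and correlation strengths (FR broader,
ρ ≈ 0.96 vs UFR ≈ 0.99). A Mahalanobis rule can exploit a covariance-shape
difference even when means coincide, so on synthetic data the multi-assay
*water* classifiers score higher (≈ 0.94–0.97) than the methanol ones
(≈ 0.87–0.92). The reported general rule — methanol beats water — holds here
for the three single-assay classifiers and on average across feature sets,
and those are the forms the test suite asserts.

## Descriptive layer

`summarize` reports min/max/median/mean per (class × solvent × assay) group;
the median of an even-sized group is the midpoint of the two central order
statistics. `pairwise_correlation` reports Pearson r, the signed squared
correlation sign(r)·r², the classical standard error of r,
σ = √((1−r²)/(n−2)), and the two-sided p-value of the exact t-test
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. The uncertainty and
p-value columns of the original publication do not exactly match any
classical formula we tried (they are consistent with the σ formula applied
to the printed value itself rather than to r); this package documents and
uses the classical formulas and makes no attempt to force agreement.

Confidence ellipses use the covariance-of-the-data convention: center =
sample mean, covariance = sample covariance (divisor n−1), threshold = the
χ²₂ quantile at the requested level (5.9915 at 0.95), so the ellipse
encloses ≈ 95 % of the *points* of a bivariate Gaussian cloud, matching the
role the ellipses play in the original figures. Boundary points count as
contained (≤). Degenerate (rank-deficient) scatters are rejected.

## The Gaussian baseline classifier

Per class c ∈ {FR, UFR}: μ_c = arithmetic mean, Σ_c = sample covariance
(divisor n_c−1). A query x is assigned to the class with the smaller
Mahalanobis distance √((x−μ_c)ᵀ Σ_c⁻¹ (x−μ_c)) — the "smaller multivariate
Z-score". Ties (probability zero for continuous data) go to FR, a fixed
documented rule. This is *not* the full Gaussian log-likelihood rule: the
log-determinant term is deliberately omitted because the distance rule is
the method being benchmarked; `classify(..., rule="loglik")` provides the
likelihood variant for sensitivity analysis. With equal class covariances
the two coincide and both equal the equal-prior Bayes rule, which is the
basis of the density-ratio oracle test and of the closed-form accuracy limit
Φ(Δ/2) at Mahalanobis separation Δ.

Covariances can be near-singular in the half-split regime (up to 6 features
fitted on ~24 training samples per class, and the water assays are almost
collinear). A relative ridge λ·mean(diag Σ)·I is escalated from 1e−8 by
decades until both class condition numbers fall below 1e8; λ = 0 is kept
when no regularization is needed, and an explicit `ridge=` pins the value
(the affine-invariance property is tested with the ridge pinned to 0).

The source description of the baseline contains one contradictory sentence
claiming parameters were estimated on *testing* data. The default here fits
on the training half, standard practice and consistent with the overall
train/test protocol; `fit_on="test"` reproduces the literal reading rather
than silently deciding the question.

## ML arms

Four scikit-learn classifiers — logistic regression, SVM, random forest,
k-nearest neighbours — under exhaustive grid search with stratified 3-fold
cross-validation on the training half, selection by mean CV accuracy
(accuracy is the study's sole metric), ties broken by grid order, refit on
the full training half. The original grids are unpublished; the defaults are
small standard grids (LR C ∈ {0.01…100}; SVM same C × {linear, RBF} ×
γ ∈ {scale, 0.1, 1}; RF {100, 300} trees × depth {2, 4, ∞}; kNN
k ∈ {1,3,5,7,9} × {uniform, distance}), all overridable. LR/SVM/kNN
standardize features with training-fold statistics because the assays differ
by an order of magnitude; RF is scale-invariant and does not. A
single-candidate grid skips cross-validation entirely (grid search
degenerates to a plain fit); the `REDUCED_GRIDS` profile uses this to make
the full jackknife sweep cheap.

## Evaluation and uncertainty

- **Accuracy** = (TP+TN)/(TP+TN+FP+FN), with UFR as the positive class (the
  choice is immaterial to accuracy and fixed only for report columns).
- **Splitting**: stratified 1/2–1/2; per label, ceil(fraction·n) samples go
  to train (51 FR → 26 train / 25 test; 47 UFR → 24/23). Deterministic given
  the seed, and shared by the baseline and every ML arm at that seed.
- **ROC/AUC**: every distinct observed value of a single assay is swept as a
  threshold; AUC by trapezoidal integration, which equals the Mann–Whitney
  pair-counting statistic with ties counted ½ (asserted against a
  brute-force oracle). Which tail of an assay indicates UFR flips between
  solvents, so orientation is auto-selected to make AUC ≥ 0.5 and recorded.
- **Jackknife comparison**: for each of the n samples, drop it, re-split the
  reduced data with a replicate-derived seed
  (`SeedSequence([master, i])`), re-optimize the baseline and the ML arm on
  the shared split, and record the accuracy difference θ_i. Point estimate =
  mean θ_i; SE = √((n−1)/n · Σ(θ_i−θ̄)²) (the classical jackknife formula,
  which reduces exactly to s/√n for the sample mean); error bars ±2 SE; a
  difference is significant only if zero lies outside the bar.

  **Limitation.** Because each replicate re-splits at random, split-to-split
  Monte-Carlo variation enters the spread of θ_i and is amplified by the
  (n−1) jackknife inflation factor, making these error bars very
  conservative (halfwidths of order 1 on the accuracy scale for the
  noisier arms). Under this construction the zero-outside rule essentially
  never fires, which is consistent with — but a much blunter instrument
  than — the original finding that no ML method significantly beats the
  baseline. Differencing on a shared split per replicate already removes
  the common split-difficulty component; the residual is the arms'
  disagreement noise. The multiplier and the whole construction are
  configurable for users who want a fixed-split or paired-replicate design
  instead.

- **Bookkeeping**: n samples × 21 feature sets × 4 ML methods gives the
  scheduled optimization count (8232 at the default 98).

## Problem sizes and numerical choices

Default analysis and test sizes: the study-scale dataset is 98 samples; the
full comparison sweep uses all 21 × 4 cells with 98 jackknife replicates
each under the reduced grids (a few minutes on one CPU); Monte-Carlo checks
use 10⁵ draws for coverage/mean recovery and moment convergence, 10⁴ per
class for the closed-form accuracy/AUC limits, and 500 replicates of n = 47
for correlation recovery. Tolerances in tests are CLT-scale bounds (4σ/√n
for means, ±0.01 absolute for limits at 10⁴–10⁵ draws). Eigenvalue floors:
1e−8 for correlation repair; covariance factorization uses an
eigendecomposition square root so exactly semidefinite inputs (degenerate
σ → 0 limits) sample correctly.
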
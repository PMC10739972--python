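# Methods

## Problem setting

`hfens` models binary in-hospital/follow-up mortality from a flat table
of 12 clinical covariates plus the `DEATH_EVENT` label (1 = dead,
0 = survived). Two properties of such registries drive the design: they
are small (hundreds of rows), and the outcome classes are imbalanced, so
empirical-risk minimisers sacrifice minority-class recall. The package's
two central components — a boosting-guided SMOTE + Tomek resampler and a
self-voted bagged hybrid classifier — address the imbalance and the
variance of small-sample fits respectively.

## Data model and preprocessing

A `ClinicalTable` is a numeric matrix with per-column `FeatureSpec`s
(name, kind ∈ {binary, integer, continuous}, unit, inclusive valid
range). The canonical schema declares the familiar heart-failure ranges
(age 40–95 y, CPK 23–7861 mcg/L, ejection fraction 14–80 %, platelets
25.01–850 kiloplatelets/mL, serum creatinine 0.5–9.4 mg/dL, serum sodium
114–148 mEq/L, follow-up 4–285 days). CSV readers validate kind and
range per cell and report the offending column and row; raw tables may
contain no missing values.

Min–max scaling maps each fitted column to `(x − min)/(max − min)`.
Three numerical conventions keep downstream algebra finite and bounded:
zero-range columns map to 0 rather than NaN; values outside the fitted
range (possible when the scaler is fitted on a training fold only) clip
to [0, 1]; and scaling is fitted on the training side of each split by
default, because fitting on the full table lets test-fold extremes leak
into training distances. A `paper_faithful` mode restores full-table
fitting for reproduction of protocols that scale before splitting.

Stratified splits take `round(n·(1 − fraction))` test rows, allocated
across classes by largest remainder, which keeps both sides within one
sample of the global class mix and makes split sizes deterministic
(299 rows at fractions 0.7/0.8/0.9 give test sizes 90/60/30). A
`repeats` option re-draws each fraction under derived seeds when paired
comparisons need more than three splits.

## Synthetic cohort generator

The generator is the package's study bench: it emulates the heart-failure
schema so every stage can be validated offline. Continuous lab values
with heavy right tails (CPK, platelets, serum creatinine) are drawn from
log-normals truncated to the declared ranges by rejection; other numerics
are uniform over their ranges; binaries are Bernoulli at registry-like
prevalences. Mortality follows a latent logistic model

    z = (1/(1+overlap)) · Σ_j w_j · standardize(x_j) + ε,  ε ~ N(0, noise_sd²)
    y ~ Bernoulli(sigmoid(z + b))

with default weights on follow-up time (−1.2), serum creatinine (+1.0),
ejection fraction (−0.8) and age (+0.6) — signed in the clinically
expected direction for death risk. The intercept `b` is solved by
bisection so the expected minority share matches the configured fraction
(default 96/299 survivors, mirroring the printed composition of the
public heart-failure registry this schema follows); the realised draw is
then trimmed to the exact count by flipping the most borderline labels.
A `STRONG_SIGNAL` preset (weights ±2/±1.5, noise_sd 0.5) is used wherever
signal-recovery behaviour itself is under test.

What the generator does **not** emulate: covariate correlations beyond
the shared latent score, censoring/survival-time structure, measurement
error, or site effects. Tests passing on synthetic cohorts therefore
certify algorithmic correctness and statistical calibration, not clinical
performance on real data.

## The resampler

1. **Boost weights.** T = 10 rounds of adaptive reweighting with a
   depth-1 stump: weighted error ε_t, stage weight
   α_t = lr·½·ln((1−ε_t)/ε_t), misclassified rows multiplied by
   exp(α_t), renormalise. ε_t = 0 stops early (weights stay uniform on
   separable data); ε_t ≥ 0.5 resets that round to uniform so a failing
   stump cannot invert the emphasis. On imbalanced tables the
   misclassified set concentrates in the minority class, so minority mean
   weight ends above majority mean weight.
2. **Weighted SMOTE.** The number of synthetic rows is
   `ceil(target_ratio · majority) − minority` (default full balance).
   Seeds are drawn from the minority class with probability proportional
   to boost weight — the channel through which the boosting stage
   "emphasises" hard minority regions — and partners uniformly from the
   seed's k = 5 minority nearest neighbours (k is lowered with a warning
   when the minority is smaller than k + 1; a single-member minority is
   an error). Interpolation is exact: `x_s = x_i + r·(x_j − x_i)`,
   r ~ U(0,1]. Binary columns copy the nearer endpoint (seed for
   r ≤ 0.5) since interpolated fractions would be invalid.
3. **Tomek cleaning** runs on the augmented table (originals plus
   synthetics). A Tomek link is a cross-class pair of mutual nearest
   neighbours under Euclidean distance; nearest-neighbour ties break
   toward the lowest row index for determinism. Only the majority member
   is removed; one pass by default, with an iterate-to-fixpoint option.

The composite returns a `ResampleReport` whose counts reconcile exactly
(after = before + synthesised − removed per class) and warns when feature
ranges suggest the table was not scaled first — Euclidean steps assume
comparable column scales.

## The hybrid classifier

Base learners (DT, GB, SVM, ET) are delegated to scikit-learn behind a
train / predict-probability contract; the SVM exposes calibrated
probabilities so a margin classifier can join a soft vote. Selection
scores validation accuracy per family and takes the argmax with ties
broken in the fixed order DT, GB, SVM, ET. Because selecting on the
final test fold leaks, the default carves a stratified 20 % of the
training fold for selection only and refits on the whole fold afterwards;
passing the test table explicitly reproduces select-on-test protocols.

Bagging draws B = 10 bootstrap resamples of size n (resamples that lose a
class are redrawn, at most 10 times) and averages member probability
vectors. The voter combines the full-fold base fit with its bagged copy:
soft voting averages the two probability vectors and takes the argmax;
hard voting falls back to the first member on disagreement (a two-member
majority needs a tie-break, and the convention keeps hard = soft whenever
members agree); weighted voting defaults to (0.5, 0.5). B = 10 balances
variance reduction against the ~15 model fits a single hybrid costs.

The ablation runner exercises a full factorial over base estimator ×
random state × voting type × feature set (ALL / FI / IG), fixing the base
family per cell, and flags the setting whose best accuracy across feature
sets attains the grid maximum — the acceptability convention of
one-tick-per-grid comparison tables. The retained defaults from those
grids are random state 10 and soft voting.

## Feature ranking

Impurity importance is the mean impurity decrease of a 100-tree random
forest, normalised to sum to 1. Information gain uses base-2 entropy;
columns with more than 10 distinct values are discretised into
equal-frequency (quantile) bins — robust to the heavy skew of CPK and
platelets, and invariant under strictly monotone transformations of the
feature. Ranking ties break alphabetically. Rankings are computed on the
scaled full table before resampling by default (resampling first would
let synthetic interpolation alter the ranking being compared); both
orderings can also be recomputed post-resampling. The top-k cut defaults
to k = 10 of the 12 predictors.

## Evaluation and inference

Metrics use the binary positive class (death): accuracy = (TP+TN)/n,
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean, ROC-AUC
by trapezoidal integration (ties give 0.5 for a constant scorer). Ratios
with zero denominators return 0 with a logged warning. Wall time and
pickled model size are recorded per fit for profiling but are
hardware-dependent and excluded from metric artifacts.

The Wilcoxon signed-rank test drops zero differences, ranks |d| with
midranks, and reports TS = min(W⁺, W⁻) — the convention under which
published comparison tables print small statistics. For n ≤ 25 the
p-value is exact: the null distribution of W⁺ is built by
shift-convolution over doubled midranks (doubling makes tied midranks
integer, so ties are handled exactly), and the two-sided p is
min(1, 2·P(W⁺ ≤ TS)), equal by symmetry to P(min(W⁺, W⁻) ≤ TS). Beyond
25 pairs a continuity-corrected normal approximation with tie-corrected
variance takes over. Under the null at n = 12 the empirical type-I error
at SL = 0.05 is ≈ 0.043 — the mild conservatism inherent to a discrete
exact test. Pairwise comparison tables pair per-split accuracy vectors;
with only three fractions the test is intentionally underpowered, which
is why the split plan supports repeats.

## Explainability

Partial dependence substitutes each grid value into every row's feature
while all other features keep their observed values (true PDP, not
at-means), averaging the model's death probability. Grids are 20
equal-frequency quantiles for numeric features and {0, 1} for binaries.
"Riskiest value ranges" are the contiguous grid intervals where the curve
exceeds mean(pd) + 0.5·sd(pd) (configurable); the threshold is a
reporting convention, not an inferential claim — a flat curve yields no
ranges, and extracted ranges are descriptive of the fitted model only.

## Pipeline and determinism

The orchestrated run wires: load/generate → rank → per-fold scale +
rebalance → train DT/GB/SVM/ET/CBCEC per split → signed-rank comparison
of all pairs → PDP and risk ranges on the selected feature subset — and
writes every artifact (input CSV, rankings, metrics JSON, WSRT table, PDP
curves, risk ranges, resample report, timing log, config snapshot). All
randomness flows from explicit seeds, so a config snapshot fully
determines every artifact; `metrics.json` excludes timings precisely so
that repeated runs are byte-identical. Default problem sizes (299-row
cohorts, 20-seed Monte-Carlo sweeps, 20 000 null replicates for test
calibration, 1000-row recovery tables) were chosen so the complete
verification suite runs comfortably on a laptop-class single core.

## Known limitations

- The generator's independence structure understates real covariate
  correlation; recovery rates on synthetic data are optimistic.
- SMOTE interpolation treats integer-kind features as continuous;
  synthetic rows may hold fractional values for them (binaries are
  protected by the endpoint rule).
- The hard-vote tie-break privileges the base member; with two voters
  this is unavoidable.
- Accuracy-based selection inherits accuracy's blindness to class
  imbalance on the validation fold; selection after rebalancing
  mitigates but does not remove this.
- Timing/space profiling is informational only and varies across
  hardware and library versions.
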
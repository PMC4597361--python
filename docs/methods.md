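# Methods

## Problem setting

Gene signatures for outcome prediction are usually assembled from the genes
with the strongest individual differential expression. combosearch
implements the complementary strategy: screen *all* pairs of expression
features (microarray probesets or genes) with a classifier that measures
the pair's **joint** discriminative power, so that a gene whose marginal
distribution barely moves between outcome groups can still surface as half
of a highly informative pair. The motivating picture is two genes whose
within-class expression is strongly correlated: the difference between them
can separate groups nearly perfectly even when each marginal overlaps
heavily. Pairs that survive the screen are grown into triples, quadruples
and quintuples by extension plus greedy refinement.

The reference application is recurrence prediction for ER-positive breast
cancer from log2-scale expression cohorts, but nothing in the code is
specific to that disease.

## Outcome classes and the gray zone

Each sample is labelled from its follow-up record:

- **positive** — event (recurrence; death-with-tumor in the RNA-seq
  setting) within `event_window` years (default 5, inclusive);
- **negative** — event-free with follow-up of at least `free_window` years
  (default 7, inclusive);
- **gray** — everything else.

Gray samples are excluded from probeset filtration, SVM fitting,
normalization, sensitivity/specificity and AUC; they re-enter only in
Kaplan-Meier plots, which use all samples. Window boundaries are treated
inclusively; both windows are parameters. The inclusive convention is a
design choice — exact-boundary follow-up times are measure-zero in real
data, so the choice is practically inert, but it is fixed and documented.

## Probeset filtration (training only)

Three rules, evaluated on the training cohort with gray samples removed:

1. drop probesets without a gene-symbol annotation;
2. drop probesets whose maximum linear expression is below
   `min_linear_expr = 128` (log2 scale 7) in every non-gray training
   sample ("constantly low");
3. drop probesets whose linear max/min ratio is below `min_ratio = 2`,
   computed as `2**(max_log2 − min_log2)` to avoid re-exponentiation error.

All three rules see only non-gray training samples, so the filter is
independent of sample order and of gray samples' values. Probesets sharing
a gene symbol remain distinct features; collapsing to unique gene sets is a
reporting view only.

## Normalization (training-frozen)

Each retained probeset is standardized by its mean and standard deviation
over non-gray training samples (sample SD, denominator n−1; the `ddof`
switch allows n). The same shift/scale pairs are applied unchanged to
filtration and validation cohorts — those cohorts are deliberately *not*
re-centered on themselves, which is what makes the frozen classifier
transferable and is why validation means are generally nonzero after
normalization.

## The classifier

A soft-margin linear SVM on the normalized tuple features, with per-class
penalty weights inversely proportional to class size,
`C_k = C · n / (2 · n_k)`, to counter the heavy class imbalance of
recurrence cohorts. The penalty factor C is selected from the grid
{1, 16, 256}: each candidate is fitted on non-gray training samples and
evaluated against the thresholds on training and every filtration cohort;
among passing candidates the one with the highest mean train∪filtration
AUC wins, ties going to the smaller C (the simpler model). The operating
point for sensitivity/specificity is the SVM's natural boundary, decision
value 0, predicting positive on strictly greater scores; ROC/AUC sweep the
threshold instead.

### Solver

The dual C-SVC problem (box constraints `0 ≤ α_i ≤ C_i`, equality
`yᵀα = 0`, unregularized bias) is solved by an in-package SMO with
second-order (maximal-violating-pair + best-gain) working-set selection and
the bias recovered from the KKT conditions of the free support vectors.
Tolerance 1e-6 on the duality gap surrogate, deterministic tie-breaks
(first index), no randomness anywhere — identical inputs give bit-identical
classifiers. The exhaustive search fits this problem ~10⁵ times per run,
which is why the solver lives in the package and is numba-compiled; its
solutions are cross-checked against libsvm (via scikit-learn's `SVC`) in
the test suite and agree to libsvm's own stopping tolerance (~1e-3 on
decision values).

Across the C grid the solver warm-starts: the dual box scales linearly in
C, so scaling the previous optimum by the C-ratio is exactly feasible and
cuts the iteration count at C=256 by roughly two orders of magnitude
without changing the solution (verified against cold starts in tests).

## Reliability metrics

Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), reported as fractions
and rendered as percentages (×100, one decimal) in report formatting. The
ROC curve is the polygonal line traced by sweeping the decision threshold
from +∞ to −∞, one vertex per distinct score; AUC is the area between the
polygon and the X-axis via the rectangle decomposition. Tied scores
produce a diagonal segment whose trapezoid contribution equals the ½-credit
of tied pairs in the Mann-Whitney formulation, so on every instance

    AUC = (#correctly ordered positive-negative pairs + ½·ties) / (n₊·n₋),

an identity the tests verify against `scipy.stats.mannwhitneyu` to 1e-12.
For tie-free scores the polygon is rectangles only. Kaplan-Meier curves
(product-limit, all samples including gray, censoring at last follow-up)
and the two-group log-rank test are delegated to `lifelines`.

## The search cascade

Every unordered pair from the filtered universe is evaluated. Acceptance
requires AUC ≥ 0.75 on training **and** ≥ 0.70 on each filtration cohort
(non-strict comparisons); the filtration cohorts exist to discard pairs
that pass on training alone — by overfitting or by chance among ~10⁸
candidates. An optional "balanced" stage additionally requires sensitivity
and specificity ≥ 0.65 on training and every filtration cohort at the fixed
threshold, removing pairs with one-sided operating points. Validation
metrics are always computed with the frozen classifier and never
participate in thresholding. Survivors are ranked by the mean
train∪filtration AUC, which also serves as the greedy criterion; ranking
ties break lexicographically by probeset tuple.

Larger combinations: each size-k tuple is extended by every universe
probeset not already in it; extensions that pass the thresholds (with the
sensitivity/specificity floors enforced by default for sizes ≥ 3) are then
greedily refined — positions are swept cyclically 1..k, at each position
every replacement is scored and the best passing one is adopted only on a
*strict* mean-AUC improvement, until a full sweep changes nothing. Strict
improvement over a finite candidate set guarantees termination. Ties keep
the incumbent; among tying replacements the earliest in universe order
wins. Results are deduplicated by unordered probeset set. Per-size
thresholds are configurable; the defaults reuse the pair thresholds.

Determinism and parallelism: the pair list is chunked into fixed-size
blocks (2048 pairs); blocks may be evaluated by any number of joblib
workers, results are merged in block order and re-sorted, so output is
byte-identical for any worker count.

## Validation statistics

Per-tuple validation AUCs are summarized by mean, median and a 95%
Student-t interval. "Mean validation AUC = 0.5" (random attribution) is
tested with a one-sample two-tailed t-test; a zero-variance sample is
handled as the degenerate limit (p → 0 unless the common value is 0.5).
Two tuple sizes are compared after a Shapiro-Wilk gate at α = 0.05 on each
sample: both normal → two-sample t-test, otherwise Mann-Whitney U (exact
enumeration for tie-free samples of n ≤ 20, tie-corrected normal
approximation beyond). Spearman rank correlation relates the
train∪filtration ranking criterion to validation AUC. The normality-gate
α and the exact/asymptotic switch are package choices where the procedure
description leaves them open.

## Synthetic data generator

The generator emulates the multi-cohort structure the method assumes; it is
the package's test bed, not a microarray simulator.

- **Planted pair.** Class-conditional bivariate Gaussians on the log2
  scale (unit within-class SD; bases 8.5 and 9.0 so the pair passes the
  expression filter). Gene 1 shifts by `delta_marginal` (default 1.0 SD —
  visible but useless alone, marginal AUC ≈ 0.76); gene 2 by `delta_gene2`
  (default 0.2 SD, marginal AUC ≈ 0.56 — "low individual differential
  expression"); the within-class correlation is solved from the requested
  joint separation `delta_joint` (default 4.0 difference-axis SDs, giving
  rho ≈ 0.98 and a pair AUC ≈ 0.998). Supplying rho explicitly overrides
  the solved value; `delta_joint = 0` degenerates to independent genes.
  The defaults were chosen once to match the qualitative two-gene picture
  (overlapping marginals, near-ideal joint separation) and are not tuned.
- **Cohorts.** Four independent cohorts (training, two filtration,
  validation) of 100 samples by default share the planted class-conditional
  distributions; each sample's expression is drawn fresh per cohort.
  One third of non-gray samples are positives — the imbalance that makes
  class-weighted penalties matter. A gray fraction (default 0.2) is drawn
  from an equal mixture of both classes, ambiguous by construction.
- **Noise.** Class-independent Gaussians with means U(7.5, 11.5) and SDs
  U(0.4, 0.8) on the log2 scale, inside the filter's passing range; rows
  that would fail the filter on the training cohort are redrawn so that
  filter tests have exact ground truth. Optional blocks are constructed to
  fail exactly one rule each: values capped below log2 128; log2 range
  clipped under 1; annotation withheld.
- **Survival.** Positives draw event times from an exponential truncated
  to the event window; negatives are censored uniformly up to three years
  beyond the free window; gray samples alternate between early censoring
  and post-window events. Outcome-class assignment applied to these tables
  reproduces the intended labels exactly (tested).
- **RNA-seq read-out.** The same latent planted-pair values mapped through
  `RPKM = scale · 2^(latent − 6 + ε)`, ε ~ N(0, 0.1) — a monotone lognormal
  re-expression that preserves decision-value ordering across platforms.

What the generator does **not** model: probe effects, batch effects,
heavy-tailed or multimodal expression, correlated noise probesets,
platform-specific missingness. Passing tests therefore demonstrate the
pipeline's contracts (recovery, false-positive control, determinism,
frozen-parameter transfer), not performance on real cohorts.

## Problem sizes and numerical choices

The packaged acceptance checks run the full cascade on one planted pair
among 200 noise probesets (~20k pairs per run) with cohorts of 100 samples,
ten seeded replicates per property — sizes chosen so the whole suite runs
on a laptop-class single core in minutes while keeping the planted-recovery
and false-positive statistics sharp. Numerical details: SMO tolerance
1e-6 with a 200k iteration guard; AUC in double precision (exact for the
rational values it takes); threshold comparisons non-strict; TSV output
with fixed 6-decimal formatting so identical runs are byte-identical.

## Known limitations

- The exhaustive screen is quadratic in the universe; a 14k-probeset
  universe (~10⁸ pairs) needs cluster-scale compute, as the original
  application did. The library parallelizes over pair blocks but does not
  distribute across machines.
- Greedy growth explores a tiny fraction of the k-tuple space and inherits
  the seed pairs' biases; it is a refinement heuristic, not a global
  optimizer.
- No multiple-testing correction beyond the filtration-cohort cascade
  itself; the cascade is the control mechanism.
- Cross-platform application assumes gene-level features can be matched by
  symbol and that a monotone transform relates the platforms' scales.
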
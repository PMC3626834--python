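# Methods

## The model

`mobrf` fits an ensemble of model-based recursive partitioning (MOB) trees.
Each tree assumes the data follow a *piecewise* generalized linear model:
the space spanned by the partition variables `z₁ … z_p` decomposes into
rectangles, and within each rectangle the outcome follows the node model

    g(E[Y | X]) = x'β,   x = (1, x₁, …, x_k)

with one of three family/link pairs: gaussian/identity (least squares),
binomial/logit and poisson/log (IRLS, canonical links). The tree algorithm
estimates the rectangles; the forest averages over the instability of that
estimate.

### Node fitting

Gaussian fits use QR-based least squares; the GLMs use iteratively
reweighted least squares with a 25-iteration cap and convergence tolerance
1e-10 on the coefficient change. Hitting the cap flags the fit
`converged=False` and makes the node terminal; a rank-deficient (or
numerically singular, via Cholesky failure of the weighted normal equations)
design raises an error at the node level and rejects the candidate during
split search. Linear predictors are clipped at ±30 before applying the
inverse link, which bounds probabilities away from exact 0/1 and Poisson
means below e³⁰; this only matters under separation, where the fit is
flagged non-convergent anyway. The per-observation estimating functions are
`(y_i − μ_i)·x_i` for all three families (the canonical-link score, dropping
the gaussian 1/σ² factor, which cancels in the decorrelated fluctuation
statistics).

### Split-variable selection

Let `s_i` be observation i's estimating-function contribution at the node's
fitted coefficients and `J = Σ s_i s_i'`. For an **ordered** partition
variable, sort by z, form partial sums `C_m`, and take

    supLM = max over admissible m of  C_m' J⁻¹ C_m / (t(1−t)),  t = m/n,

where m ranges over boundaries between distinct z values with
`trim ≤ t ≤ 1−trim` (trim default 0.10). Its asymptotic null law — the
supremum of a squared tied-down Bessel process over the trimmed interval —
has no closed form; `mobrf` evaluates p-values against a Monte-Carlo table
(20 000 Brownian-bridge paths on a 1000-point grid, simulated once per
(number of coefficients, trim) with a fixed internal seed and cached for the
process lifetime). P-values are floored at 1/(table size + 1): the table
cannot resolve smaller tails, and a strictly positive floor guarantees that
`alpha → 0` always yields a single-node tree. In finite samples the test is
mildly conservative (measured null rejection at n = 200, alpha = 0.05 is
≈ 0.03–0.05), because the observed maximum runs over ~n candidate
breakpoints rather than the continuum; this is the usual behaviour of
supLM-type tests against asymptotic critical values.

For a **categorical** variable with L levels (at most
`max_categorical_levels`, default 10) the statistic is the level-sum
chi-square `Σ_l (n/n_l) S_l' J⁻¹ S_l` with `S_l` the within-level score sum,
referred to χ² with (L−1)·k degrees of freedom (p-value floored at 1e-300).
For an intercept-only gaussian model this reduces exactly to the classical
one-way score statistic n·SSB/SST, which the tests exploit as an oracle.

The variable with the smallest p-value is selected if it is below `alpha`;
with `bonferroni=True` p-values are first multiplied by the number of
variables tested in that node (the mtry subset — those are the comparisons
actually made), capped at 1. Ties go to the earliest variable in the tested
order. `alpha` defaults to 1, so splitting by default proceeds until the
sample-size rules stop it; single-tree practice often uses 0.05 instead.

### Cutpoint search

Given the selected variable, the cutpoint maximizes the sum of the two
children's maximized log-likelihoods (equivalently, for gaussian, minimizes
the pooled SSE), subject to both children containing at least `minsplit`
rows and fitting non-singularly. Ordered variables scan every midpoint
between consecutive distinct values; the gaussian scan uses prefix sums of
X'X and X'y so each candidate costs one small Cholesky solve, while the GLM
scan warm-starts each candidate's IRLS from the previous candidate's
solution. Categorical variables scan all 2^(L−1) − 1 binary level
partitions. Objective ties keep the smallest threshold / lexicographically
first partition, so trees are deterministic.

### Tree growth and prediction

Nodes stop when n < 2·minsplit, the node fit fails to converge, no tested
variable clears alpha, or no admissible cutpoint exists. A fresh uniform
mtry-subset of partition variables is drawn (without replacement) at *every
node* — the per-node reading of random feature selection, matching standard
random-forest practice. Prediction routes each row by the split rules
(`≤ threshold` left; level ∈ left set left) to a terminal node and evaluates
that node's model on the response scale (probabilities for logistic). A
categorical level unseen during training routes left, with a warning. Trees
serialize to an indented text rendering and a round-trip-safe JSON form.

## Forest

Defaults: `ntree=300`, `mtry = max(1, floor(p/3))`, subsampling without
replacement with `fraction=0.632` (so every tree's in-bag size is exactly
`floor(0.632·n)`), or bootstrap with `replace=True` (n draws, expected OOB
fraction (1−1/n)ⁿ → e⁻¹ ≈ 0.368). Tree k's random stream is derived from
`SeedSequence([seed, k])`, so results are bit-identical for any `processors`
value (workers via joblib/loky only change wall time). Per-subject
aggregates report the mean of the present per-tree predictions, their sample
(n−1) standard deviation (0 when only one tree contributes), and — for
gaussian and poisson only — the residual observed − mean; subjects never OOB
(possible at small ntree) are reported missing rather than silently falling
back to in-bag predictions, which would break the honesty of OOB estimates.
For the binomial family the residual column is omitted and flagged in
`DataFrame.attrs`.

## Accuracy

Per-tree metrics are computed on each tree's own OOB cases; forest-level
metrics first average OOB predictions per subject across trees and then
score the means. Pseudo R² is clamped to zero whenever negative, at both
tree and forest level (the clamp is stated for trees; extending it to the
forest keeps the documented [0, 1] range). Binary outcomes report PCC after
thresholding at `prob_cutoff` (a probability exactly at the cutoff
classifies as 1 — a fixed, tested tie rule) plus a Brier-style MSE on the
probabilities as a secondary column; the forest-level PCC thresholds the
*mean* OOB probability with the same cutoff. AUC uses the rank-based
Wilcoxon–Mann–Whitney statistic with midranks for ties. A constant outcome
on an evaluation set leaves R² undefined (error for the direct call, NaN
with a warning inside forest aggregation, e.g. when `fraction=1` leaves no
OOB cases).

## Permutation importance

For tree k and variable m, the variable's values among that tree's OOB cases
are permuted once and the OOB metric recomputed with the tree's predictions;
the contribution is MSE_permuted − MSE (continuous) or PCC − PCC_permuted
(binary), so larger is always more important. (A literal reading of the
usual MSE subtraction order would make important variables negative; both
orientations are flipped to degradation-positive for internal consistency
with the permutation-importance literature.) The raw score is the mean
contribution over all trees. Permutation streams are keyed by (forest seed,
tree index, CRC32 of the variable name), so reordering the variable list
permutes the scores without changing any value. Variables that appear in no
split rule and not in the node model cannot change predictions and score
exactly 0; that identity is short-circuited rather than recomputed, with
identical results.

## Synthetic data generator

`fixtures` draws partition variables (independent standard normals by
default, optionally correlated through a Gaussian-copula Cholesky factor;
categorical levels uniform unless overridden), node-model predictors, and
optional uniform treatment-group assignment with reference-coded dummies.
Each row must satisfy exactly one subgroup predicate (validated at runtime);
its linear predictor uses that subgroup's coefficients, and the outcome adds
gaussian noise, or draws Bernoulli(logit⁻¹(η)) or Poisson(exp(η)). Named
fixtures:

- `two_subgroup_gaussian` — n=500, y = ±x + ε split at z01 = 0, noise SD
  0.5, nine pure-noise partition variables. The ±1 slopes against SD-0.5
  noise give a strong, but not degenerate, recovery problem: single trees
  should find z01 at the root and forests should rank it first essentially
  always.
- `poisson_two_subgroup` — count outcome with a rate-ratio flip at z01 = 0.
- `combine_like` — n=987 (echoing an 80% training split of an 8-arm
  alcohol-dependence trial), binomial outcome, node model = baseline
  severity covariate (uniform 0–100, slope −0.03 per point) + 7 treatment
  dummies, 40 partition variables (35 numeric, 5 three-level categorical).
  The 8 true subgroups form a depth-3 tree over z01–z05 with intercepts in
  {−1.5, −0.5, 0.5, 1.5} and treatment-effect vectors of alternating sign,
  so all five variables are informative. Its demo run settings (alpha 0.5,
  Bonferroni, minsplit 40, cutoff 0.5) mirror the stricter policy typical
  for a confirmatory subgroup analysis.

What passing tests on these fixtures show — and what they do not: the data
satisfy the MOB model exactly (axis-aligned subgroups, correctly specified
node model, independent covariates, no missingness). Real trial data violate
all of these to some degree, so recovery rates here are upper bounds on
practical performance, not estimates of it.

## Problem sizes and numerical choices

The test suite and acceptance script size their simulations to desk scale as
a design choice: calibration uses 1000 null replicates at n = 200; recovery
uses 100 replicates with 25-tree forests at n = 500; the binomial demo uses
20 trees. Forest quality improves slowly beyond that for these generators,
and the assertions are on rates and inequalities, not on ensemble-size-
dependent constants. Tolerances: estimating-function column sums vanish to
1e-6 (relative); the categorical statistic matches its brute-force oracle to
1e-8; degenerate-ensemble prediction SDs are zero up to the rounding of a
mean of n identical doubles (~1e-16).

## Known limitations

- Binary splits only; no surrogate splits, missing-value routing, pruning,
  case weights, offsets, interactions or additional GLM families.
- The supLM p-value inherits Monte-Carlo error from the cached table
  (standard error ≈ 0.0015 at p = 0.05) and cannot resolve p below ~5e-5.
- Exhaustive GLM cutpoint search is O(n) IRLS fits per selected variable and
  node; it is exact but the dominant cost for logistic/Poisson forests.
- OOB aggregation ignores bootstrap multiplicities: a case drawn twice is
  simply in-bag.
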
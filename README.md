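# mobrf — random forests of model-based recursive partitioning trees

`mobrf` builds ensembles of **model-based recursive partitioning (MOB)
trees** for subgroup discovery and stable prediction in clinical and
epidemiological data. Where CART-style trees split so that the *response* is
homogeneous within nodes, a MOB tree fits a parametric regression — the
*node model* — inside every node and splits where that model's
**coefficients** are unstable across a partition variable. Terminal nodes
therefore carry distinct fitted models, e.g. subgroup-specific treatment
effects in a randomized trial:

```
g(E[Y]) = β₀ + β₁X + β₂T₂ + … + β_J T_J
```

with `g` the identity, logit or log link (linear, logistic or Poisson node
model), `X` a baseline covariate and `T₂ … T_J` reference-coded treatment
dummies. A single tree is unstable under small perturbations of the
learning sample, so `mobrf` grows many trees on bootstrap or subsampled
replicates, tests only a random subset of `mtry` partition variables at each
node (the random-forest ingredient), and aggregates predictions across
trees.

What the package computes:

- **Split selection** by score-fluctuation tests: a supLM statistic over the
  trimmed breakpoint range for ordered partition variables, a level-sum
  chi-square for categorical ones; the most unstable variable below `alpha`
  (optionally Bonferroni-corrected) is split at the cutpoint maximizing the
  children's summed log-likelihood (pooled SSE for gaussian).
- **Out-of-bag (OOB) accuracy**: per-tree and forest-level pseudo
  `R² = max(0, 1 − SSE/SSTO)` and MSE for continuous outcomes; proportion
  correctly classified (PCC, default probability cutoff 0.5) for binary
  outcomes; AUC via the Wilcoxon–Mann–Whitney statistic.
- **Permutation variable importance**: mean degradation of OOB accuracy
  across trees when a variable's OOB values are permuted
  (degradation-positive: larger = more important).
- **Plots**: variable importance, predictive-accuracy panels, and OOB
  residual diagnostics (linear node model only).

## Worked example

```python
from mobrf import MobForest, ForestControl, fixture_spec, generate_subgroup_data

# synthetic two-subgroup data: y = ±x + ε, sign flips at z01 = 0,
# z02..z10 are pure noise partition variables
data, truth = generate_subgroup_data(fixture_spec("two_subgroup_gaussian", seed=7))
test, _ = generate_subgroup_data(fixture_spec("two_subgroup_gaussian", n=200, seed=1007))

model = MobForest(
    data, "y ~ x", [f"z{i:02d}" for i in range(1, 11)],
    family="gaussian",
    control=ForestControl(ntree=100, mtry=4, seed=1),
    test_data=test,
)
results = model.fit()
print(results.summary())
```

prints

```
Model-based recursive partitioning forest
=========================================================
node model:      y ~ x
family:          gaussian_identity
partition vars:  10
n obs:           500
ntree:           100   mtry: 4   subsample 0.632
mob controls:    alpha=1.0 bonferroni=False minsplit=20
---------------------------------------------------------
per-tree OOB r2:  min 0.000  median 0.682  max 0.810
forest OOB r2:    0.7677
forest OOB MSE:   0.2882
test r2:          0.7864   test MSE: 0.2768
---------------------------------------------------------
top variables (raw permutation importance):
   1. z01              1.71802
   2. z07              0.01184
   3. z03              0.01158
   4. z08              0.00596
   5. z05              0.00287
```

The forest explains ~77% of the OOB outcome variance (the generative model
caps attainable R² at 1 − 0.5²/Var(y) ≈ 0.8 here), and permutation
importance isolates the one truly informative partition variable `z01` by
two orders of magnitude. `results.predicted(oob=True)` returns the
per-subject mean OOB prediction, its across-tree standard deviation and the
residual; `results.plot_importance(...)`, `.plot_accuracy(...)` and
`.plot_residuals(...)` write the diagnostic figures plus CSVs of the plotted
numbers.

The same analysis runs from the shell:

```sh
mobrf run --fixture two_subgroup_gaussian --ntree 100 --seed 1 --out out/
mobrf fixtures list
mobrf fixtures generate combine_like demo.csv --seed 1
```

`mobrf run` accepts a YAML config (`--config cfg.yaml`) with flag overrides
and writes predictions, accuracy JSON/CSV, importance CSV, plots and a
manifest with artifact hashes. The `combine_like` fixture emulates an 8-arm
2×2×2 factorial treatment trial with a binary responder outcome, a logistic
node model with 7 treatment dummies, and 40 partition variables of which 5
define the subgroups.

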
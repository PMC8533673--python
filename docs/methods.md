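# Methods

## The model

`divforest` implements *diversity forests*: ensembles of binary
classification trees in which the candidate splits of every node are
obtained by **split sampling** rather than exhaustive search. A *split
problem* is the set of all admissible binary splits involving one feature
(or, for interaction forests, one feature pair). At each node the algorithm
repeats, `nsplits` times: (1) sample a split problem uniformly **with
replacement** over features, (2) sample one split uniformly from that
problem. The best candidate by Gini impurity decrease is used. Because
problems are drawn with replacement, a candidate set may contain several
(even duplicate) splits from the same feature — this is deliberate and is
the structural difference from extremely randomized trees, which draw a
fixed number of cut-points per distinct sampled feature.

Small nodes are protected from candidate-set overfitting by the `proptry`
rule: with `total` the number of all admissible splits at the node (summed
over features), the number of draws is reduced to `floor(proptry * total)`
whenever `nsplits` exceeds `proptry * total`. A reduction to zero makes the
node terminal, so with the recommended `nsplits = 30` and `proptry = 0.05`
growth stops at any node offering fewer than 20 splits.

Three univariable selectors are interchangeable node policies:

* `df` — the split-sampling rule above;
* `rf` — conventional random-forest selection: `mtry` features drawn
  without replacement, every node-local threshold of each evaluated;
* `extr` — extra-trees selection: `mtry` features without replacement, `k`
  cut-points per feature drawn continuous-uniform on the node-local
  (min, max) range (`k = 1` is the classical rule, `k = 5` the five-cut
  variant).

DF cut-points are uniform over the node-local midpoint thresholds while
`extr` cut-points are continuous-uniform; the two sampling laws are kept
deliberately distinct because they induce different distributions over
admissible splits.

### Interaction forests

The `pair` selector implements bivariable splitting for interaction
detection. A pair split problem on features (j1, j2) offers seven split
types: one univariable split per member, four "quantitative" splits whose
left child is one ≤/> quadrant of the (j1, j2) plane, and one "qualitative"
split whose left child is the union of the lower-left and upper-right
quadrants (the diagonal region that captures XOR-type signal, where the
direction of one feature's effect depends on the other). The five
bivariable splits of a problem share a single split-point pair, drawn
uniformly from each member's node-local thresholds. Per node at most 10
problems are sampled with replacement, giving at most 70 candidate splits.
For data with more than 100 features, 5000 feature pairs are pre-selected
by a screening score: the best Gini decrease of a qualitative split on a
coarse 3×3 quantile grid minus the best univariable decrease of either
member (computed for all pairs at once via indicator-matrix products). The
score targets interaction-specific signal and is documented as replaceable.
No `proptry` reduction is applied to pair splitting; the candidate caps
play that role.

## Tuning and evaluation protocol

Hyperparameters are chosen by out-of-bag (OOB) error: one forest of
`trees_per_candidate` trees (default 1000) per grid setting, the setting
with the smallest OOB misclassification rate wins (exact ties fall to the
first setting in grid order), and a final forest of `final_trees` trees
(default 2000) is refit at the winner. The recommended DF grid fixes
`nsplits = 30` and chooses `proptry` from {0.05, 1}; the dense 7×7
sensitivity grid {2, 5, 10, 30, 50, 100, 200} × {0.01, 0.05, 0.1, 0.3,
0.5, 0.8, 1} is available for pre-study-style analyses. For `rf`/`extr`,
`mtry` is tuned on the grid {1, …, p} when p ≤ 20 and otherwise on
{[i^(log p / log 20)] : i = 1..20} (round half away from zero,
deduplicated; the bracket in that construction is ambiguous between floor
and round — rounding was chosen and is trivially swappable).

The benchmark harness runs stratified five-fold cross-validation repeated
twice (fresh shuffles per repetition). Performance is measured by ACC
(threshold 0.5), AUC (ties counted 1/2) and the Brier score. Held-out
predictions are pooled within a repetition, each measure computed once per
repetition, and per-dataset values are the mean over repetitions before
cross-dataset quartiles (type-7 quantiles) are taken. Methods are compared
by two-sided Wilcoxon signed-rank tests on per-dataset values (zero
differences dropped, ties mid-ranked; exact null up to 25 non-zero pairs,
continuity-corrected normal approximation beyond) with effect size
r = |Z|/√N.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| `nsplits` | candidate draws per node (df) | 30 | performance is flat above ~30 |
| `proptry` | small-node draw cap, fraction of all splits | tuned from {0.05, 1} | 1 = no cap; 0.05 additionally stops growth at nodes with < 20 splits |
| `mtry` | features per node (rf/extr) | tuned on the grid above | classical behaviour |
| `k` | cut-points per feature (extr) | 1 | 5 gives the five-cut variant |
| `min_node_size` | smallest splittable node | 1 | fully grown classification trees |
| `resample_mode` | bootstrap / subsample | bootstrap, size n | conventional default; subsampling by option |
| pair caps | problems/node, splits/problem, screened pairs, screening threshold | 10, 7, 5000, 100 | bounds the per-node work at 70 candidates |
| interaction-forest trees | ensemble size for pair splitting | 20000 exposed; tests use far fewer | interaction signal needs many trees because pair sampling is dilute |

Leaves predict the class-1 training fraction and the forest averages leaf
probabilities (a probability forest), since AUC and Brier are evaluated.
OOB tuning uses misclassification at 0.5 by default; a Brier-based OOB
error is available (`oob_measure="brier"`).

## Randomness and determinism

All randomness flows from a single integer seed. Tree `t` of a forest uses
`SeedSequence(seed, spawn_key=(t+1,))`; the selector's one-off preparation
(pair screening) uses spawn key `(0,)`; tuning derives one stream per grid
setting. Fits, tuning runs, CV folds and generators are bit-reproducible
given the seed, and model JSON round-trips predictions exactly (IEEE
doubles survive Python's JSON encoding).

## Synthetic data

The generators produce the structures the method's claims rest on, not any
particular real dataset:

* `gen_marginal` — balanced Bernoulli(0.5) labels; signal features are
  class-conditional unit-variance normals whose means differ by `effect`
  (so `effect` is a standardized mean shift: 0.2 weak, ≥ 2 strong); noise
  features are independent standard normals; optional label flips.
* `gen_xor` — planted feature pairs with label `1[(x_a > 0) ≠ (x_b > 0)]`,
  combined across pairs by majority (random tie-break bit); planted
  features have ~zero marginal association with the label, isolating
  interaction-only signal.
* `gen_dataset_battery` — a deterministic collection cycling weak
  (effect ≤ 0.3), strong (effect ≥ 2) and interaction-only regimes with
  n ∈ [100, 600], 2–5 signal and 5–40 noise features.
* categorical features are emulated by quantile-binning a continuous
  column (3–5 bins), exercising the loader's integer-encoding path.

What these generators do **not** emulate: correlated features, non-Gaussian
marginals, class imbalance, label-dependent missingness, and the
heterogeneity of real repositories. Passing tests therefore demonstrate
algorithmic correctness and qualitative behaviour (separable data is
solved, null data stays at chance, interaction-only signal is visible to
pair splits and invisible to univariable ones), not real-data rankings of
the methods.

## Numerical choices

* Thresholds are midpoints between consecutive distinct node-local values,
  so rules are stable on test data; degenerate splits (an empty child)
  carry a −∞ criterion and are never selected; criterion ties are broken
  uniformly at random.
* `floor(proptry * total)` is computed with a 1e-9 guard because the true
  product is rational and binary floating point may land a hair under an
  integer.
* Split-problem draws landing on currently constant features are re-drawn,
  with total attempts bounded at 10× the required draws.
* Categorical columns are integer-encoded by ascending class-1 frequency
  of their categories (ties by category value), keeping the ordered-split
  machinery meaningful; missing values are rejected at load time with the
  offending column and row named.
* Tuning tie-break: first setting in grid order. OOB rows with zero
  coverage are excluded from the error; a forest whose every row is in-bag
  yields a NaN error rather than a silent number.

## Known limitations

* The node-count comparison between `proptry = 0.05` and `proptry = 1` is
  monotone only in the few-feature regime (p ≤ ~4 at n ≈ 300), where the
  small-node stopping rule is the operative mechanism. At larger p the
  reduction instead thins candidate sets at small nodes; the weaker chosen
  splits purify more slowly and 0.05-trees can end up *larger* than
  1.0-trees. Measured: at p = 10, n = 400 the 0.05-trees were larger in
  30/30 seeded trials. The stopping rule itself (terminal below 20
  available splits) holds at any p.
* `proptry` selection under OOB tuning is close to a coin flip on
  weak-signal data at moderate-to-large p, because the reduction only
  affects nodes with fewer than `nsplits/proptry` total splits (< 13 rows
  at p = 50): both settings then produce nearly the same forest. Exact OOB
  ties fall to 0.05 (first grid entry).
* Interaction forests sample pair problems uniformly, so with many
  features the planted pair is hit at rate 10/#pairs per node; at a few
  hundred trees this dilution means only a modest predictive edge over
  univariable forests on planted-XOR data — far more trees (the 20000
  default) or pre-screening to a short pair list concentrate the signal.
  The *root-split* contrast is unambiguous at any ensemble size: the
  qualitative split attains a Gini decrease ≥ 0.4 on planted-XOR data
  where every univariable split stays ≤ 0.02.
* OOB error is mildly pessimistic relative to a large independent holdout
  (each OOB prediction averages ~e⁻¹ of the trees, each trained on ~63%
  of distinct observations); the measured absolute gap at n = 1000 with
  500 trees is ≤ ~0.05 on moderate-signal data.
* Only binary outcomes are supported; survival/ordinal criteria,
  unordered categorical partition splits, multi-way splitting and the
  effect-importance measure of interaction forests are out of scope.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script forests are scaled for a desk run:
200–500 trees, n = 400–1000, 5-fold CV with one or two repetitions, 50
oracle fixtures, 20-replicate tuning studies. The protocol defaults
(1000/2000 trees, 5×2 CV) remain the package defaults.
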
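# Methods

## The community hub model

`comhub` estimates which candidate regulators (typically transcription
factors) are hubs — regulators with many targets — in the gene
regulatory network underlying one expression dataset.  The premise is
that although individual network-inference methods rank specific
regulator→target edges poorly and inconsistently, a regulator's
*outdegree* is a sum over many edge predictions, so averaging outdegrees
across methods yields a far more stable statistic than any per-edge
consensus.

Given N ranked edge-list predictions over a shared regulator set of size
R, the pipeline is:

1. **Outdegree at a threshold.**  For a prediction *l* and an
   edge-inclusion threshold *T*, `outdegree_kl` is the number of targets
   of regulator *k* among the top-*T* edges of *l*.  Confidence ties at
   the cut boundary are resolved by stored list order; loaders and
   engines sort stably (descending confidence, then regulator/target id),
   so reruns are bitwise reproducible.
2. **Threshold selection.**  For each candidate *T* the mean pairwise
   Pearson correlation of the N outdegree vectors is computed; the
   selected *T* maximizes it, with ties broken toward the smallest
   threshold (the sparser network).  Pairs in which either vector is
   constant are excluded — a constant vector carries no ranking
   information — and a threshold where every pair is excluded is skipped.
   The rationale: the meta-prediction is best defined where the ingoing
   methods agree most about who the hubs are, and that agreement peak
   empirically tracks the accuracy peak when the compendium is diverse
   (see "Known limitations").
3. **Averaging.**  `score_k = (1/N) Σ_l outdegree_kl` at the selected
   threshold; regulators absent from a prediction contribute 0, so all
   score vectors have length R and `0 ≤ score_k ≤ T`.  Regulators are
   ranked by descending score, ties broken by identifier.

The default candidate grid is log-spaced —
{100, 200, 500, 1000, 2000, 5000, 10⁴, 2·10⁴, 5·10⁴, 10⁵} intersected
with [1, max |edges|] — covering optima from desk-scale benchmarks to
genome-wide predictions; it is user-overridable.

A per-edge comparator, `edge_rank_community`, implements the classic
consensus that averages each edge's rank across methods; an edge absent
from method *m* contributes rank |list_m| + 1 (monotone, simple, and
aware of each method's list length).

## Inference engines

Six engines map (expression, regulators) to a ranked edge list.  All are
deterministic given a seed; one global seed fans out to the stochastic
engines through fixed per-engine offsets so adding an engine never
shifts another engine's stream.  Targets include all genes (regulators
may regulate regulators); a regulator is never its own target.

- **pcc** — |Pearson correlation| of regulator and target profiles.
  Zero-variance genes get confidence 0 with a logged warning.
- **clr** — mutual information with background correction: for edge
  (i, j), z_i is the positive part of MI_ij z-scored against row i of
  the MI matrix, z_j likewise against column j, confidence
  √(z_i² + z_j²).  MI uses equal-frequency discretization (default 10
  bins, so any monotone transform of the data gives identical output,
  matching the tool's scale-agnostic posture) and the maximum-likelihood
  plug-in estimator, in nats.
- **aracne** — the same MI pair set pruned by the data-processing
  inequality: in every triangle with all three MI values defined (i.e.
  at least two regulator vertices), the weakest edge is removed when its
  MI < (1 − tolerance) × the smaller of the other two, strictly;
  removals are decided on the original MI values and applied at once.
  Default tolerance 0; tolerance 1 disables pruning.  Survivors are
  ranked by MI.
- **genie3** — per-target random-forest regression on the regulator
  profiles; the confidence of (regulator, target) is the regulator's
  variance-reduction importance, normalized per target to sum 1 (0 for
  constant targets).  Defaults: 1000 trees, **all** features considered
  per split.  With a small regulator panel, subsampling features (the
  "sqrt" rule) makes the importances nearly marginal — credit leaks to
  regulators that merely correlate with the true parent — which both
  degrades the ranking and collapses the engine onto the correlation
  family, costing the compendium its diversity.  Considering all
  features keeps the regression properly conditional; "sqrt" remains
  available as the usual speed/accuracy trade for large panels.
- **elasticnet** — bootstrap elastic net (default 1000 resamples,
  l1_ratio 0.5): the confidence is the fraction of bootstrap resamples
  in which the regulator's coefficient is nonzero.  The regularization
  strength is chosen per target on the full data by a small
  cross-validated grid (7 log-spaced values) and held fixed across
  resamples, so the confidence is a pure selection frequency.
- **tigress** — stability selection over randomized least-angle
  regression (published defaults: 1000 resamples in paired half-sample
  splits, 5 LARS steps, multiplicative regulator weights uniform on
  [0.2, 1]).  The confidence is the area score: the mean over steps
  s = 1..L of the frequency with which the regulator entered within the
  first s steps.

Profiles are standardized internally where the method requires scale
invariance (elastic net, TIGRESS); correlation and MI engines use raw
profiles.

## Evaluation

Performance against a gold standard is the Pearson (or Spearman)
correlation between predicted hub scores and gold-standard regulator
outdegrees, computed over the *full* regulator set including
zero-outdegree regulators — deterministic, and it punishes false hubs.
For undirected (protein-interaction proxy) standards, degree over all
partners stands in for outdegree.  Two further diagnostics: the mean
absolute difference of degree *fractions* (both vectors normalized to
sum 1, since mean outdegrees and gold counts live on different scales),
and HITS hub scores of the thresholded prediction graph (power iteration
of the hubs/authorities recurrence, unit-Euclidean normalization per
iteration, stopping when the hub vector changes by < 1e-10 or after
1000 iterations).

## WGCNA-style comparator

The standard alternative hub pipeline, used as a baseline: unsigned soft
adjacency a_ij = |cor|^β with β chosen as the smallest candidate whose
scale-free-topology fit (signed R² of the log-log degree-distribution
regression, negative slope required) reaches 0.8; topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij); average-
linkage clustering on 1 − TOM with a static cut at 0.99 × the maximum
merge height plus a minimum module size (default 20); eigengenes are the
first principal components of the standardized module submatrices, sign-
oriented toward their members; modules whose eigengenes correlate above
1 − 0.25 are merged iteratively.  Regulators are ranked by kME — the
absolute correlation with their own module's eigengene, falling back to
the maximum over modules for unassigned regulators so every regulator is
rankable.  The static cut is a simplified, parameterized stand-in for
dynamic tree cut: the comparator needs representative module structure,
not the full adaptive algorithm.  Clustering is performed in sorted-gene
order so module labels are invariant to input order.

## Synthetic benchmark

The generator produces the structure the predictor targets, with no
external data:

- **Network.**  Regulator sampling weights ∝ rank^(−α) over a random
  permutation (α = `outdegree_exponent`, default 2.0), targets uniform;
  `n_edges` distinct pairs are drawn (default 600 over 300 genes and 20
  regulators).  The regulator→regulator subgraph is kept acyclic by
  admitting only edges that run forward in a fixed random topological
  order.  That order is drawn *independently* of the outdegree weights:
  hierarchy position and hub size are separate properties, and tying the
  heaviest hub to the top of the hierarchy would let one
  regulator→regulator edge hand the entire regulon to a downstream
  regulator, swamping the gold tail with inherited correlations.
- **Expression.**  Linear-Gaussian: unregulated genes are standard-
  normal sources; each regulated gene is Σ (w_e × parent profile) +
  N(0, noise_sd²) with per-edge weights w_e ~ N(0, effect_sd²), evaluated
  in topological order (defaults: 200 samples, effect 1.0, noise 0.5).
  A linear model — rather than kinetic ODE simulation — keeps noiseless
  limits exactly checkable (regulated genes lie exactly in the span of
  their parents) while preserving the planted-hub detectability that the
  benchmark is for.

What the generator does *not* emulate: saturating/combinatorial
regulation, feedback through non-regulator genes, measurement-specific
noise (counts, batch effects), and realistic regulator panel sizes
(R = 20 versus hundreds of TFs in genome-scale compendia).  Passing
tests therefore demonstrate the pipeline's correctness and its behaviour
under heavy-tailed, linearly detectable hub structure — not performance
on any particular real dataset.

## Benchmark configuration and numerical choices

- The standard benchmark (`default_fixture`, seed 42) is 300 genes / 20
  regulators / 600 edges / 200 samples.  Behavioural tests and the
  acceptance script run GENIE3 with 100 trees (the package default is
  1000): with ≤ 19 features and 200 samples the importances are stable
  well below 100 trees, and the benchmark then completes on a single
  CPU in about a minute.
- Pairwise outdegree correlations use the centered dot-product form, so
  identical vectors score exactly 1.0 and the smallest-threshold
  tie-break is well defined.
- Ties everywhere (edge ranks, hub ranks, module renumbering) break by
  identifier; all randomness flows from explicit seeds; per-target
  engine seeds are spawned from the engine seed so results do not depend
  on target iteration order.
- Degenerate inputs fail loudly: missing expression values, constant
  vectors in correlation metrics, empty thresholded graphs, and all-
  undefined threshold scans raise typed errors rather than returning
  silent defaults.

## Known limitations

- The agreement-based threshold rule assumes a *diverse* compendium.
  When the ingoing methods share their biases — e.g. several
  correlation-family engines on the same data — they also agree on
  indirect-correlation structure, and the agreement peak can drift past
  the accuracy peak.  Conditional engines (tree ensembles, sparse
  regression) or ARACNE's pruning restore the correspondence; running at
  least one of them alongside the marginal engines is recommended.
- With few regulators (R ≈ 20) the pairwise Pearson similarity is
  dominated by the largest hub; rankings over large regulator panels
  discriminate thresholds more sharply.
- Hub scores are mean outdegrees: the regulatory strength of individual
  regulator→target edges should not be interpreted from them.
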
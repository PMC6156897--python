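# Methods

## Problem setting and model

`dtiscope` casts drug–target interaction (DTI) discovery as binary
classification over fused transcriptome signatures. The inputs are Level-4
style Z-score profiles over n landmark genes (n = 978 in the real assay),
one set of replicate trials per drug perturbation and per gene knockdown.
The gold standard is an edge list of known (drug, gene) interactions.

The central modelling assumptions are:

* a drug's expression signature carries a recoverable imprint of its
  targets' knockdown signatures, so the joint vector [x_drug, x_gene] is
  informative about whether the pair interacts;
* replicate trials of one entity are noisy realizations of a common
  signature, possibly contaminated by outlier trials, so a small credible
  set of aggregated profiles represents the entity adequately;
* pairs whose gene is a known target of *some* drug but without a recorded
  edge cannot be treated as negatives — they are the prediction universe
  (unlabeled); true negatives are pairs whose gene targets nothing.

## Replicate aggregation

For an entity with t replicate trials, the trial–trial Pearson correlation
matrix is computed and the trials are partitioned by k-means (Euclidean
distance on the raw Z-score vectors, 10 restarts, seeded) with

| replicate count t | k |
|---|---|
| ≤ 2 | no clustering |
| 3–5 | 2 |
| 6–15 | 3 |
| > 15 | 4 |

Boundary counts (5, 15) go to the smaller k, so the rule is closed and
monotone. The *intra-class correlation* of a cluster is the mean of its
pairwise Pearson correlations; a singleton scores 1.0 by convention.
Because that convention would otherwise hand the arg-max to any isolated
outlier trial, only clusters with at least two members compete for the
representative when any exist. S1 is the centroid of the winning cluster
(ties broken toward the lowest cluster label); S2 is the grand mean of all
trials, kept so no replicate information is discarded. If S1 and S2 agree
to 1e-9 per element, one row is kept. Every downstream sample uses one
credible-set row per entity side, and all row combinations of an entity
pair inherit the pair's label.

## Sample construction

Fusion is exact serial concatenation, drug block first — no scaling or
transformation — giving 2n-dimensional samples (1956 at full landmark
width). The pair trichotomy (positive / unlabeled / negative) follows the
label matrix as above. Negatives are selected *at uniform intervals*: the
negative row space is ordered canonically (gene-major, then drug,
lexicographic; credible-set rows in order) and indices
floor(j·|space|/needed), j = 0..needed−1, are taken, with
needed = round(ratio · #positives), rounding half away from zero, and
ratio defaulting to 2. This reading makes the draw deterministic and
platform-independent; a seeded uniform-random alternative is available via
the `rng` argument / `--random-negatives`. Cross-validation folds are
stratified by label and assigned at entity-pair granularity so that no
pair's row combinations straddle the train/validation boundary.

## Classifier and objective

The network is fully connected with ReLU hidden activations and a two-unit
softmax output (computed with max-subtraction); CM_{i,0} and CM_{i,1} are
the negative- and positive-class probabilities. The training objective per
batch of size m is

    (1/m) [ Σ_i ( −y_i ln p_i − (1−y_i) ln(1−p_i) )  −  η Σ_{i: y_i=0} CM_{i,0} ]

with p_i = CM_{i,1}. The penalty is subtracted exactly as specified, so the
objective is unbounded below by −η and may be negative; it rewards
confident negative-class probability on true negatives and thereby lowers
the fraction of unlabeled pairs called positive (PoPC) at a small cost in
validation accuracy. Probabilities are clipped to [ε, 1−ε], ε = 1e-7,
inside the logarithms (the penalty term uses the raw probability; it needs
no clipping). The same ε clips the logit in the D-score so rankings stay
finite.

Numerical and training choices:

* **Initialization** — He-normal weights (σ = √(2/fan_in)), zero biases,
  drawn from the run's seed. The scheme is the standard choice for ReLU
  stacks; nothing else was tried.
* **Gradients** — derived analytically (for the two-class softmax,
  ∂p/∂z = p(1−p)·(−1, +1)) and checked against central differences at
  relative 1e-4 in a standing test.
* **Optimizer** — minibatch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
  learning rate 1e-4, batch size 128, 200 epochs, with optional early
  stopping on validation loss (patience 20, best weights restored). The
  batch size and epoch count are package defaults; they are not dictated
  by the method.
* **Dropout** — rate 0.5, inverted scaling, applied after each hidden
  activation only (not on input or output); inference runs with dropout
  off and is deterministic.
* **Determinism** — all randomness flows from explicit seeds; a fixed seed
  and dataset reproduce the final weights bitwise on one thread.
* **η = 10** is the full-scale default. On desk-scale pools of a few
  hundred positives the same weight drives the objective into the trivial
  all-negative solution before the interaction signal is learned, so the
  packaged recovery experiment uses η = 1 with learning rate 1e-3 (see
  below). The monotone effect of η — raising it over {0, 10, 100} does not
  raise the mean positive-class probability on true negatives — is a
  standing test of its own.

## Evaluation statistics

* **Accuracy / F-score** at threshold 0.5 on held-out folds (the logit's
  zero point makes 0.5 the natural hard-call boundary); zero-denominator
  precision or recall is reported as 0 with a flag.
* **PoPC** — fraction of unlabeled pairs with p > 0.5; at fixed accuracy a
  lower PoPC marks a more conservative predictor.
* **Predictive error** between a comparator model and the network:
  PE(x) = CM^other at the true class − CM^net at the true class; negative
  values favour the network. Antisymmetry under swapping the models is a
  standing test.
* **D-score ranking** of unlabeled pairs, ties broken lexicographically by
  (drug, gene) for run-to-run stability. Row-combination probabilities are
  averaged to entity-pair level before ranking.
* **Sliding-window overlap** against an independent reference edge list:
  windows of `bin_width` consecutive ranks (default 500), sliding by
  `step` (default 1; `step = bin_width` gives disjoint bins). Counts obey
  |Δ| ≤ 2·step between consecutive windows, and disjoint windows sum to
  the prefix overlap — both asserted as properties.

## The synthetic panel generator

The generator plants a known interaction structure so that every stage can
be tested offline:

* every gene g carries a latent signature s_g (i.i.d. standard normal over
  the landmark features, unit-normalized);
* knocking down g centres trials on −signal_strength · s_g (loss of
  function inverts the signature);
* a drug centres on signal_strength · Σ s_g over its planted targets;
* each trial adds i.i.d. Gaussian noise (sd `trial_noise_sd`, default 0.5);
* with probability `outlier_fraction` a trial is a *mismatch*: its planted
  signature is replaced by an unrelated random direction of the same scale,
  the way a swapped or failed well still yields a full-amplitude Z-score
  profile rather than low-amplitude technical noise;
* drug targets are drawn from a druggable subset of the genes
  (`druggable_fraction`, default 0.25). Real gold standards concentrate a
  few hundred targets among thousands of profiled knockdowns, with several
  drugs sharing each target; that multiplicity is what allows any
  classifier to generalize across pairs. With targets spread uniformly over
  all genes, most target genes carry a single edge, most validation
  positives involve genes never seen as targets in training, and held-out
  accuracy plateaus regardless of capacity or training time.

What the generator does *not* emulate: cell-line, dose and time covariates;
inference of non-landmark genes; heavy-tailed or correlated noise;
per-feature standardization (profiles are left as unstandardized Gaussians
— the pipeline nowhere depends on marginal scaling). Passing tests on this
generator therefore demonstrate the pipeline's mechanics and its ability to
recover planted structure, not performance on real assay data.

## The recovery experiment

`recovery_experiment(recovery_panel_config(seed))` is the package's
end-to-end check: 120 drugs × 120 genes, 64 landmark features, 1–3 targets
per drug from a 30-gene druggable subset, 1–25 trials per entity (so every
k-selection branch is exercised), signature scale 2.0 against trial noise
0.5. A quarter of the planted edges is withheld; the rest form the label
matrix. The reduced network 2n–32–8–2 is evaluated by five-fold stratified
cross-validation (η = 1, learning rate 1e-3, batch 128, up to 1200 epochs
with early stopping on fold-validation loss at patience 50); reported
accuracy and F-score are fold means. Unlabeled pairs are scored by the fold
models' ensemble-mean probability, aggregated to entity-pair level, ranked
by D-score, and the sliding-overlap curve against the withheld edges is
summarized by its top- and bottom-decile means. Ensembling and early
stopping matter here: a single fully-trained fold model sometimes memorizes
the identities of a well-connected gene's known partner drugs and then
actively down-ranks that gene's novel true partners. The panel size was
chosen so each druggable target carries roughly the number of positive
examples per target that a full-scale gold standard provides (≈10); the
feature count is reduced from 978 to keep the experiment inside seconds on
one CPU.

Typical results (panel seeds 0–9): cross-validated accuracy 0.89–0.97 and a
1.1–6× enrichment of withheld true edges in the top decile of the ranking
relative to the bottom decile.

## Known limitations

* Under the positive/unlabeled/negative trichotomy, training negatives
  never share a gene with training positives, so gene identity alone
  separates the training classes. On the synthetic panel the classifier
  partly exploits this: most unlabeled pairs (whose genes are all genuine
  targets) receive high probabilities, which is why PoPC is large there
  and why the D-score *ranking*, not the hard call, carries the discovery
  signal. The same structural property exists in the real labelling
  scheme.
* The subtracted penalty makes the objective scale-sensitive: the useful
  range of η depends on the positive count, as described above.
* k-means with a forced k larger than the natural number of trial clusters
  can split a coherent replicate group; the credible-set selection then
  averages fewer trials than the grand mean. The mismatch outlier model
  keeps S1 ahead of S2 in that regime; with genuinely outlier-free data
  S2 is often the slightly better representative, and keeping both rows in
  the credible set is the hedge.
* Training determinism is guaranteed on a single thread; multi-threaded
  BLAS reductions may reorder sums.
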
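# Methods

## Problem

Given a binary disease x miRNA association matrix `A` (nd x nm), per-disease
MeSH-style ancestor DAGs, and a miRNA functional-similarity matrix `FS`, the
package ranks every *unknown* cell of `A` (a "candidate") by its plausibility
of being a true association.  The driving assumption is guilt by association:
functionally similar miRNAs tend to associate with semantically similar
diseases, so the similarity structure around a pair carries information about
the pair itself.

## Similarity layer

**Semantic similarity, model 1.**  A disease `D` is a DAG of its ancestor
terms.  Each term `d` contributes

    DD(d) = 1                                if d = D
    DD(d) = max { delta * DD(d') : d' child of d }   otherwise

with semantic contribution factor `delta` in (0, 1] (default 0.5, the usual
convention for MeSH-based disease similarity; configurable).  The semantic
value is `D1(D) = sum_d DD(d)` and two diseases are similar in proportion to
the contributions of shared terms:

    SS1(i, j) = sum_{k in T(i) ∩ T(j)} (DD_i(k) + DD_j(k)) / (D1(i) + D1(j)).

Because contributions decay geometrically along the best path, `DD(d)` equals
`delta ** (shortest path length from d to D)`; the test suite checks the
recurrence against an independent path-enumeration oracle.

**Semantic similarity, model 2.**  Terms that appear in few disease DAGs are
more specific and should weigh more.  Model 2 replaces the per-disease
contribution by a global information-content weight

    DD'(d) = -log( #DAGs containing d / #diseases )

(natural log; a term present in every DAG contributes exactly 0, which is a
legitimate limit, not an error) and applies the same shared-mass formula.
The disease semantic matrix `SS` is the entrywise average of SS1 and SS2.

**Gaussian interaction-profile (GIP) kernels.**  The interaction profile of
a disease is its row of `A` (column for a miRNA).  The kernel is

    K(x, y) = exp( -alpha * ||IP(x) - IP(y)||^2 ),
    alpha   = alpha' / mean(||IP||^2)

with raw bandwidth `alpha' = 1` by default (the standard choice for
interaction-profile kernels; configurable).  The denominator is the average
number of interactions per entity, so the kernel is scale-free in the matrix
density.

**Integration.**  The integrated disease similarity `SD` takes the semantic
value where *both* diseases have a DAG and the kernel value otherwise; `SM`
does the same with `FS` versus the miRNA kernel.  "Has semantic similarity"
is read as "has a DAG"; a flag (`semantic_mode="positive"`) instead falls
back to the kernel wherever the semantic entry is exactly zero, for users
who prefer that reading.

## Feature layer

Pair (d(i), m(j)) is described by stacking column i of `SD` over column j of
`SM`: an (nd + nm)-vector in [0, 1].  Known associations form matrix `T`
(one column per positive).  Negatives are drawn uniformly without
replacement from the unknown cells, as many as there are positives,
seeded and logged.  All unknown cells form the candidate matrix `AT`;
candidates sampled as training negatives are still scored and ranked like
any other candidate.  `PT` (positives at classification time) is identical
to `T` and shares its code path.

## Sparse auto-encoder

Each layer is a sigmoid encoder/decoder with untied weights trained
full-batch to minimise

    J_sparse = (1/n) sum_i 1/2 ||k(x_i) - x_i||^2
             + (delta_wd / 2) * sum W^2
             + beta * sum_j KL( rho || rho_hat_j )

where `rho_hat_j` is unit j's mean activation over the sample set and
`KL(p||q)` is the Bernoulli Kullback-Leibler divergence.  Design choices:

* weight decay applies to encoder and decoder weights, never biases
  (`regularize_decoder=False` restricts it to the encoder);
* the decoder output is a sigmoid, matching inputs in [0, 1];
* optimisation is deterministic L-BFGS (default 400 iterations) from a
  seeded Uniform(-r, r) initialisation with r = sqrt(6 / (n_in + n_out));
* `rho_hat` is clipped to [1e-8, 1 - 1e-8] with a warning if a unit
  saturates, keeping the KL term finite;
* `delta_wd` defaults to 1e-4 — small enough not to bias reconstruction,
  large enough to keep weights bounded.

Layers are pretrained greedily — each on the previous layer's encodings of
the positive-association matrix `T` — and then frozen; there is no
supervised fine-tuning.  For the sparsity target of the second stacked
encoder, "mean hidden activation" refers to the current auto-encoder's own
hidden layer.  The full-scale default stack is input -> 250 -> 80 with
`beta = 5`, `rho = 0.05`.

## Classifier and ranking

A soft-margin linear SVM (default `C = 1`) separates encoded positives from
encoded negatives.  Candidates are scored by the signed Euclidean distance
`(w . x + b) / ||w||` to the hyperplane, oriented so training positives
score positive on average; since the distance is a positive rescaling of
the decision value, rankings are identical either way.  Within each disease
candidates are sorted by descending score, ties broken lexicographically by
miRNA label so output is deterministic.  An RBF kernel is available behind
a flag (scores are then raw decision values) but is not the supported
default.

## Cross-validation

*Global LOOCV* holds out each known association in turn and ranks it
against every candidate cell; *local LOOCV* ranks it only against
candidates of the same disease (held-out pairs whose disease has no
candidates are excluded with a warning); *k-fold CV* (default k = 5)
partitions the positives at random, holds out each part, and repeats the
whole procedure over independent partitions (default 10), reporting the
mean and SD of the AUC.

Per fold, by default:

* the held-out pairs are zeroed in `A` *before* the GIP kernels are
  recomputed (semantic similarity depends only on the DAGs and is computed
  once);
* negatives are resampled from the reduced matrix, excluding the held-out
  cells, with fold-derived seeds;
* the auto-encoder is retrained on the remaining positives.

This is the leak-free protocol; `frozen_similarity` (kernels from the full
matrix) and `pretrain_once` (one encoder for all folds) reproduce cheaper
variants and are labelled in the output config snapshot.  If a fold has
fewer unknown cells than training positives (only possible on nearly dense
toy matrices), the negative set is capped at availability with a warning.

Each fold scores with its own model, so raw scores are not comparable
across folds.  Scores are therefore reduced to within-fold candidate
percentiles (fraction of that fold's candidate scores strictly below, ties
counted half) before pooling; the reported AUC is the Mann-Whitney
statistic of pooled held-out percentiles versus pooled candidate
percentiles, which equals the trapezoidal area under the pooled ROC curve
exactly (a test asserts agreement to 1e-12).

## Synthetic data

The generator plants the structure the method assumes, so recovery under
cross-validation is a meaningful end-to-end test:

* an ancestor forest with `n_shared_ancestors` roots; each disease attaches
  as a leaf under a random node, so shared path prefixes induce graded
  semantic similarity;
* latent vectors drift down the forest (ancestor drift 0.45, leaf drift
  0.35); miRNA latents sit around cluster centres (drift 0.45); each entity
  also carries a N(0, 0.8) scalar propensity emulating the heavy hub
  structure of curated association databases;
* association probabilities follow a logistic link in the latent inner
  product plus both propensities, temperature 0.25 (a sharp, nearly
  deterministic planted signal), shifted by bisection so the mean
  probability equals the target density.  The realised matrix must land
  within 20% relative of the target plus three standard errors of the
  realised mean — the allowance keeps ordinary binomial fluctuation on
  small matrices from masquerading as calibration failure;
* sampling uses common random numbers keyed by the disease latent, so
  diseases with identical latents get identical rows (exactly testable);
  optional independent bit flips add label noise;
* every entity is guaranteed at least one association so the pair-list
  serialisation preserves label sets;
* `FS` is the affine map (1 + cos) / 2 of miRNA latent cosine similarity.

What the generator does **not** emulate: real MeSH DAG topology (depth,
fan-in), the long-tailed degree distribution of curated databases beyond a
Gaussian propensity, annotation biases, or noise correlated with similarity.
Passing recovery tests therefore shows the pipeline can exploit planted
similarity-aligned structure at small scale — not that it attains any
particular accuracy on real association databases.

## Scaled-down evaluation protocol

Tests and the acceptance script run on a 30 x 40 fixture (density 0.15, no
label noise, generator seed 7; about 200 positives and 1000 candidates), a
size chosen so full leave-one-out with per-fold retraining stays cheap.
The full-scale stack (250/80, `beta = 5`) targets an 878-row input; at 70
rows the same settings over-compress, because the reconstruction term
scales with input width while the KL penalty scales with hidden width
(relative sparsity pressure ~ `beta * n_hidden / n_in`).  The scaled
protocol therefore uses hidden sizes [64, 48], `beta = 1` (matching the
full-scale relative pressure), `rho = 0.05` unchanged (it is a per-unit
target rate, dimensionless), and `C = 30` — encoded activations live in a
narrow band around `rho`, so margins are small and a larger soft-margin
cost is appropriate.  Full-scale defaults are untouched.

Under this protocol the planted-structure fixture gives global LOOCV AUC
around 0.88, bracketed by the planted-probability oracle (~0.97) above and
the random-score null (~0.50) below; local LOOCV is lower (~0.78), as
expected when ranking within single diseases.

## Known limitations

* Semantic similarity assumes disease labels match DAG targets exactly; no
  vocabulary mapping is attempted.
* The linear SVM scores pairs additively in the encoded space; interaction
  structure must be captured by the encoder's nonlinearity.
* Accuracy on real association databases depends on the specific database
  snapshot and on hyperparameters with no single canonical value (`delta`,
  raw kernel bandwidths, weight decay, SVM cost, log base in model 2);
  all of them are explicit, configurable and logged here, and reported
  AUCs should always be read together with that configuration.
* LOOCV retrains everything per fold; on full-scale data (thousands of
  positives) use `frozen_similarity`/`pretrain_once` or k-fold CV.
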
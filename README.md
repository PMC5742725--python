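# drmda

Deep-representation prediction of miRNA–disease associations.

Many human diseases are linked to microRNAs, but experimentally testing
every disease–miRNA pair is infeasible; curated databases cover only a
sliver of the true association matrix.  `drmda` ranks the *unknown* cells
of a binary disease × miRNA association matrix by how likely they are to be
real associations, for researchers prioritising candidate miRNAs for
follow-up.  It rests on the usual guilt-by-association premise: similar
diseases tend to involve functionally similar miRNAs.

## Method

Given the association matrix `A` (nd × nm), per-disease MeSH-style ancestor
DAGs, and a miRNA functional-similarity matrix `FS`:

1. **Integrated similarities.**  Disease semantic similarity is the average
   of two DAG-overlap models — one with per-edge decay `Δ` of an ancestor's
   contribution (`DD(d) = max Δ·DD(child)`, `SS1 = Σ_shared (DD_i+DD_j) /
   (D1_i+D1_j)`), one weighting terms by information content
   (`DD′(d) = −log(#DAGs containing d / #diseases)`).  Where a disease has
   no DAG (or a miRNA no functional-similarity entry), a Gaussian
   interaction-profile kernel on the rows/columns of `A` fills in:
   `K(x,y) = exp(−α‖IP(x)−IP(y)‖²)` with `α = α′ / mean‖IP‖²`.  The result
   is an integrated disease matrix `SD` and miRNA matrix `SM`.
2. **Deep representation.**  Each pair (d(i), m(j)) becomes the
   (nd+nm)-vector [SD column i ; SM column j].  A stacked sparse
   auto-encoder (default 878 → 250 → 80 at full scale; sigmoid units,
   KL-divergence sparsity penalty `β Σ_j KL(ρ‖ρ̂_j)`, L2 weight decay) is
   pretrained greedily, layer by layer, on the known-association columns
   only, then frozen.
3. **Scoring.**  A linear soft-margin SVM separates encoded positives from
   an equal number of sampled negatives; every candidate cell is scored by
   signed distance to the hyperplane and ranked per disease.

Accuracy is assessed by global/local leave-one-out cross-validation and
repeated five-fold cross-validation with a rank-based (Mann–Whitney)
ROC/AUC.  By default every fold removes the held-out association *before*
kernels are recomputed, resamples negatives, and retrains the encoder, so
no fold sees its own answer.  See `docs/methods.md` for the full model
description, parameter table and design rationale.

## Worked example

The package ships a synthetic-data generator that plants the structure the
method assumes (DAG-derived disease similarity, clustered miRNAs, low-rank
logistic associations with hub propensities), so everything runs without
downloads:

```python
from drmda import FixtureConfig, simulate_dataset, PipelineConfig, TrainingConfig, run_pipeline

data = simulate_dataset(FixtureConfig(nd=12, nm=16, density=0.18, seed=11))
cfg = PipelineConfig(
    ae=TrainingConfig(layer_sizes=[28, 16, 8], beta=1.0, max_iter=200),
    svm_c=10.0,
    seed=0,
)
predictions, report = run_pipeline(data, cfg)
print(f"{report['n_positives']} known associations, {report['n_candidates']} candidates")
for disease, mirna, score, rank in predictions.rows[:5]:
    print(f"{disease}\t{mirna}\t{score:+.3f}\t{rank}")
```

prints

```
43 known associations, 149 candidates
d00	m09	+0.160	1
d00	m03	+0.153	2
d00	m13	+0.143	3
d00	m14	+0.142	4
d00	m12	+0.141	5
```

i.e. of disease `d00`'s unknown cells, miRNA `m09` lies farthest on the
positive side of the SVM hyperplane (score is signed distance in the
encoded space) and is that disease's top candidate.

The same workflow is available as a console tool operating on TSV files:

```
drmda simulate --nd 30 --nm 40 --density 0.15 --seed 7 --outdir data/
drmda similarity --assoc data/associations.tsv --dags data/dags.tsv --fs data/fs.tsv \
                 --out-sd data/sd.tsv --out-sm data/sm.tsv
drmda train    --assoc data/associations.tsv --sd data/sd.tsv --sm data/sm.tsv \
               --layers 64,48 --beta 1.0 --out data/model.json
drmda predict  --model data/model.json --assoc data/associations.tsv \
               --sd data/sd.tsv --sm data/sm.tsv --out data/predictions.tsv
drmda evaluate --assoc data/associations.tsv --dags data/dags.tsv --fs data/fs.tsv \
               --mode kfold --k 5 --repeats 10 --layers 64,48 --report report.json
```

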
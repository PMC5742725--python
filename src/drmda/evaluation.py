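"""Cross-validation protocols and rank-based ROC/AUC.

Protocols
---------
* **global LOOCV** — each known association is held out in turn; the model
  is refit without it and the held-out pair is ranked against every
  candidate (unknown) cell.
* **local LOOCV** — as global, but the held-out pair is ranked only against
  candidate cells of the same disease.
* **k-fold CV** — the known associations are randomly partitioned; each
  part is held out in turn and its pairs are ranked against all candidate
  cells; the whole procedure is repeated over independent partitions and
  the mean and SD of the AUC are reported.

By default each fold removes the held-out associations *before* the
interaction-profile kernels are computed, resamples negatives, and retrains
the auto-encoder — nothing the model sees encodes the held-out edge.  Two
cheaper variants are available: ``frozen_similarity`` keeps the full-data
kernels, and ``pretrain_once`` trains the encoder stack a single time on
all positives.

Because each fold scores with its own model, scores are reduced to
within-fold candidate percentiles before pooling; the AUC is the
Mann-Whitney statistic of held-out percentiles versus candidate
percentiles (ties count one half), which equals the area under the pooled
ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .features import candidate_pairs, sample_negatives
from .io import AssociationMatrix, Dataset
from .pipeline import PipelineConfig, compute_similarities, derive_seed, fit_predictor
from .similarity import disease_semantic_matrix

__all__ = [
    "CVResult",
    "FoldContext",
    "FoldInfo",
    "FoldRecord",
    "rank_based_auc",
    "global_loocv",
    "local_loocv",
    "loocv",
    "kfold_cv",
    "random_scorer",
    "make_oracle_scorer",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class CVResult:
    """ROC points, AUC and provenance for one validation protocol."""

    mode: str
    roc_points: np.ndarray  # (k, 2) of (FPR, TPR), (0,0) .. (1,1)
    auc: float
    seed: int
    config: dict
    per_fold_auc: list[float] | None = None  # k-fold only: AUC per repetition
    auc_sd: float | None = None
    n_folds: int = 0


@dataclass
class FoldContext:
    """Everything a scoring function may use inside one fold."""

    fold_index: int
    assoc_reduced: AssociationMatrix
    sd: object
    sm: object
    train_pos: list[Pair]
    negatives: list[Pair]
    score_pairs: list[Pair]
    seed: int
    dataset: Dataset


@dataclass(frozen=True)
class FoldInfo:
    """Instrumentation record emitted per fold (leakage auditing)."""

    held_out: tuple[Pair, ...]
    assoc_reduced: AssociationMatrix
    ae_train_pairs: tuple[Pair, ...]
    svm_pos_pairs: tuple[Pair, ...]
    svm_neg_pairs: tuple[Pair, ...]


@dataclass(frozen=True)
class FoldRecord:
    held_out: tuple[Pair, ...]
    test_scores: np.ndarray
    candidate_pairs_: tuple[Pair, ...]
    candidate_scores: np.ndarray


def rank_based_auc(test_scores: Sequence[float], candidate_scores: Sequence[float]) -> float:
    """Mann-Whitney AUC of test versus candidate scores, ties counted half.

    Equivalent to sweeping a rank threshold: the probability that a random
    test sample outranks a random candidate.
    """
    test = np.asarray(test_scores, dtype=float)
    cand = np.asarray(candidate_scores, dtype=float)
    if test.size == 0 or cand.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([test, cand]))
    u_stat = ranks[: test.size].sum() - test.size * (test.size + 1) / 2.0
    return float(u_stat / (test.size * cand.size))


def _percentiles(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Fraction of ``ref`` strictly below each value, ties counted half."""
    ref_sorted = np.sort(np.asarray(ref, dtype=float))
    vals = np.asarray(values, dtype=float)
    lo = np.searchsorted(ref_sorted, vals, side="left")
    hi = np.searchsorted(ref_sorted, vals, side="right")
    return (lo + 0.5 * (hi - lo)) / ref_sorted.size


def _roc_points(test_vals: np.ndarray, cand_vals: np.ndarray) -> np.ndarray:
    labels = np.concatenate([np.ones(test_vals.size), np.zeros(cand_vals.size)])
    scores = np.concatenate([test_vals, cand_vals])
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def _pipeline_scorer(ctx: FoldContext, cfg: PipelineConfig, frozen_layers) -> np.ndarray:
    fold_cfg = replace(cfg, seed=ctx.seed)
    predictor = fit_predictor(
        ctx.sd, ctx.sm, ctx.train_pos, ctx.negatives, fold_cfg, layers=frozen_layers
    )
    return predictor.score_pairs(ctx.score_pairs)


def random_scorer(ctx: FoldContext) -> np.ndarray:
    """Permutation-null baseline: i.i.d. uniform scores."""
    return np.random.default_rng(ctx.seed).random(len(ctx.score_pairs))


def make_oracle_scorer(simulated) -> Callable[[FoldContext], np.ndarray]:
    """Score pairs by the generator's planted association probability."""
    assoc = simulated.associations
    probs = simulated.planted_probability

    def scorer(ctx: FoldContext) -> np.ndarray:
        return np.array(
            [probs[assoc.disease_index(d), assoc.mirna_index(m)] for d, m in ctx.score_pairs]
        )

    return scorer


def _run_folds(
    dataset: Dataset,
    folds: Sequence[Sequence[Pair]],
    cfg: PipelineConfig,
    scorer: Callable[[FoldContext], np.ndarray] | None = None,
    fold_hook: Callable[[FoldInfo], None] | None = None,
) -> list[FoldRecord]:
    assoc = dataset.associations
    positives = assoc.positive_pairs()
    candidates = tuple(candidate_pairs(assoc))
    # semantic similarity depends only on the DAGs: compute once
    ss = disease_semantic_matrix(dataset.dags, cfg.delta) if dataset.dags else None
    sd_full = sm_full = None
    if cfg.frozen_similarity or cfg.pretrain_once:
        sd_full, sm_full, _ = compute_similarities(assoc, dataset.dags, dataset.fs, cfg, ss=ss)
    frozen_layers = None
    if cfg.pretrain_once:
        from .autoencoder import greedy_pretrain
        from .features import build_feature_matrix

        t_full = build_feature_matrix(positives, sd_full, sm_full, role="T")
        ae_cfg = replace(cfg.ae, seed=derive_seed(cfg.seed, "ae"))
        frozen_layers = greedy_pretrain(t_full.values, ae_cfg)

    records: list[FoldRecord] = []
    for f_idx, held in enumerate(folds):
        held = tuple(held)
        held_set = set(held)
        train_pos = [p for p in positives if p not in held_set]
        assoc_reduced = assoc.without(held)
        if cfg.frozen_similarity:
            sd, sm = sd_full, sm_full
        else:
            sd, sm, _ = compute_similarities(
                assoc_reduced, dataset.dags, dataset.fs, cfg, ss=ss
            )
        fold_seed = derive_seed(cfg.seed, "fold", f_idx)
        n_available = len(assoc_reduced.zero_pairs()) - len(held_set)
        n_neg = min(len(train_pos), n_available)
        if n_neg < len(train_pos):
            warnings.warn(
                f"only {n_neg} unknown cells available for {len(train_pos)} positives; "
                "negative set is smaller than the positive set",
                stacklevel=2,
            )
        negatives = sample_negatives(
            assoc_reduced, n_neg, seed=derive_seed(fold_seed, "neg"), exclude=held_set
        )
        score_list = list(candidates) + list(held)
        if fold_hook is not None:
            fold_hook(
                FoldInfo(
                    held_out=held,
                    assoc_reduced=assoc_reduced,
                    ae_train_pairs=tuple(positives) if cfg.pretrain_once else tuple(train_pos),
                    svm_pos_pairs=tuple(train_pos),
                    svm_neg_pairs=tuple(negatives),
                )
            )
        ctx = FoldContext(
            fold_index=f_idx,
            assoc_reduced=assoc_reduced,
            sd=sd,
            sm=sm,
            train_pos=train_pos,
            negatives=negatives,
            score_pairs=score_list,
            seed=fold_seed,
            dataset=dataset,
        )
        if scorer is None:
            scores = _pipeline_scorer(ctx, cfg, frozen_layers)
        else:
            scores = np.asarray(scorer(ctx), dtype=float)
        n_cand = len(candidates)
        records.append(
            FoldRecord(
                held_out=held,
                test_scores=scores[n_cand:],
                candidate_pairs_=candidates,
                candidate_scores=scores[:n_cand],
            )
        )
    return records


def _summarise(
    records: Sequence[FoldRecord],
    mode: str,
    cfg: PipelineConfig,
    local: bool = False,
) -> CVResult:
    test_pool: list[np.ndarray] = []
    cand_pool: list[np.ndarray] = []
    n_folds = 0
    for rec in records:
        if not local:
            cand_scores = rec.candidate_scores
            if cand_scores.size == 0:
                warnings.warn("fold has no candidate cells; excluded", stacklevel=2)
                continue
            test_pool.append(_percentiles(rec.test_scores, cand_scores))
            cand_pool.append(_percentiles(cand_scores, cand_scores))
            n_folds += 1
        else:
            for t_idx, (disease, _) in enumerate(rec.held_out):
                sel = np.array(
                    [d == disease for d, _ in rec.candidate_pairs_], dtype=bool
                )
                cand_scores = rec.candidate_scores[sel]
                if cand_scores.size == 0:
                    warnings.warn(
                        f"disease {disease!r} has no candidate cells; fold excluded",
                        stacklevel=2,
                    )
                    continue
                test_pool.append(
                    _percentiles(rec.test_scores[t_idx : t_idx + 1], cand_scores)
                )
                cand_pool.append(_percentiles(cand_scores, cand_scores))
                n_folds += 1
    if not test_pool:
        raise ValueError("no scorable folds")
    test_vals = np.concatenate(test_pool)
    cand_vals = np.concatenate(cand_pool)
    auc = rank_based_auc(test_vals, cand_vals)
    return CVResult(
        mode=mode,
        roc_points=_roc_points(test_vals, cand_vals),
        auc=auc,
        seed=cfg.seed,
        config=cfg.to_dict(),
        n_folds=n_folds,
    )


def loocv(
    dataset: Dataset,
    cfg: PipelineConfig | None = None,
    scorer: Callable[[FoldContext], np.ndarray] | None = None,
    fold_hook: Callable[[FoldInfo], None] | None = None,
) -> dict[str, CVResult]:
    """Run leave-one-out folds once; summarise globally and locally."""
    cfg = cfg or PipelineConfig()
    positives = dataset.associations.positive_pairs()
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    folds = [[p] for p in positives]
    records = _run_folds(dataset, folds, cfg, scorer=scorer, fold_hook=fold_hook)
    return {
        "global": _summarise(records, "global_loocv", cfg, local=False),
        "local": _summarise(records, "local_loocv", cfg, local=True),
    }


def global_loocv(dataset: Dataset, cfg: PipelineConfig | None = None, **kwargs) -> CVResult:
    return loocv(dataset, cfg, **kwargs)["global"]


def local_loocv(dataset: Dataset, cfg: PipelineConfig | None = None, **kwargs) -> CVResult:
    return loocv(dataset, cfg, **kwargs)["local"]


def kfold_cv(
    dataset: Dataset,
    k: int = 5,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
    repeats: int = 10,
    scorer: Callable[[FoldContext], np.ndarray] | None = None,
    fold_hook: Callable[[FoldInfo], None] | None = None,
) -> CVResult:
    """Repeated k-fold CV over random partitions of the known associations."""
    cfg = cfg or PipelineConfig()
    if seed is None:
        seed = cfg.seed
    positives = dataset.associations.positive_pairs()
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(positives):
        raise ValueError(f"k={k} exceeds the {len(positives)} known associations")
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    aucs: list[float] = []
    first_result: CVResult | None = None
    for rep in range(repeats):
        rng = np.random.default_rng(derive_seed(seed, "partition", rep))
        perm = rng.permutation(len(positives))
        folds = [[positives[i] for i in part] for part in np.array_split(perm, k)]
        rep_cfg = replace(cfg, seed=derive_seed(seed, "repeat", rep))
        records = _run_folds(dataset, folds, rep_cfg, scorer=scorer, fold_hook=fold_hook)
        result = _summarise(records, "kfold", rep_cfg, local=False)
        aucs.append(result.auc)
        if first_result is None:
            first_result = result
    return CVResult(
        mode="kfold",
        roc_points=first_result.roc_points,
        auc=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else None,
        per_fold_auc=aucs,
        seed=seed,
        config=cfg.to_dict(),
        n_folds=k * repeats,
    )
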
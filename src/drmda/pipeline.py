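"""End-to-end prediction pipeline.

The three stages: (1) build integrated similarity matrices SD/SM from
semantic similarity, functional similarity and the association-profile
kernels; (2) assemble per-pair feature columns and learn the stacked sparse
auto-encoder on the known (positive) associations; (3) train a linear SVM on
encoded positives versus an equal number of sampled negatives and score
every candidate cell by signed hyperplane distance, ranked per disease.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .autoencoder import (
    AutoencoderLayer,
    TrainingConfig,
    greedy_pretrain,
    save_stack,
    stack_encode,
)
from .classifier import SVMModel, rank_candidates, score_samples, train_svm
from .features import build_feature_matrix, candidate_pairs, sample_negatives
from .io import (
    AssociationMatrix,
    Dataset,
    RankedPredictions,
    SimilarityMatrix,
    write_predictions,
)
from .similarity import disease_semantic_matrix, gip_kernel, integrated_similarity

__all__ = [
    "PipelineConfig",
    "FittedPredictor",
    "compute_similarities",
    "fit_predictor",
    "run_pipeline",
    "derive_seed",
    "config_hash",
]


@dataclass
class PipelineConfig:
    """All tunables of the predictor, with every seed explicit."""

    delta: float = 0.5
    alpha_prime: float = 1.0
    ae: TrainingConfig = field(default_factory=TrainingConfig)
    svm_c: float = 1.0
    svm_kernel: str = "linear"
    seed: int = 0
    semantic_mode: str = "dag"  # or "positive": fall back to kernel where SS == 0
    frozen_similarity: bool = False  # CV option: keep full-data kernels per fold
    pretrain_once: bool = False  # CV option: train the auto-encoder once on all positives

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if out["ae"]["layer_sizes"] is not None:
            out["ae"]["layer_sizes"] = list(out["ae"]["layer_sizes"])
        return out


def derive_seed(base: int, *keys) -> int:
    """Stable sub-seed derivation; result fits in a signed 32-bit int."""
    material = [int(base)] + [
        int(k) if isinstance(k, (int, np.integer)) else zlib_crc(str(k)) for k in keys
    ]
    return int(np.random.SeedSequence(material).generate_state(1)[0] & 0x7FFFFFFF)


def zlib_crc(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode())


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def compute_similarities(
    assoc: AssociationMatrix,
    dags: Mapping,
    fs: SimilarityMatrix | None,
    cfg: PipelineConfig,
    ss: SimilarityMatrix | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix | None]:
    """Integrated disease (SD) and miRNA (SM) similarity from one association matrix.

    ``ss`` may carry a precomputed semantic matrix (it depends only on the
    DAGs, not on the associations) to avoid recomputation across CV folds.
    """
    kd, _ = gip_kernel(assoc, "diseases", cfg.alpha_prime)
    km, _ = gip_kernel(assoc, "mirnas", cfg.alpha_prime)
    if ss is None and dags:
        ss = disease_semantic_matrix(dags, cfg.delta)
    sd = integrated_similarity(ss, kd, mode=cfg.semantic_mode)
    sm = integrated_similarity(fs, km, mode=cfg.semantic_mode)
    return sd, sm, ss


@dataclass
class FittedPredictor:
    """Frozen encoder stack + SVM, bound to the similarity matrices it was fit on."""

    layers: list[AutoencoderLayer]
    model: SVMModel
    sd: SimilarityMatrix
    sm: SimilarityMatrix

    def score_pairs(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        feats = build_feature_matrix(pairs, self.sd, self.sm, role="AT")
        return score_samples(self.model, stack_encode(self.layers, feats.values))


def fit_predictor(
    sd: SimilarityMatrix,
    sm: SimilarityMatrix,
    pos_pairs: Sequence[tuple[str, str]],
    neg_pairs: Sequence[tuple[str, str]],
    cfg: PipelineConfig,
    layers: list[AutoencoderLayer] | None = None,
) -> FittedPredictor:
    """Stage 2 + 3: pretrain the stack on positives (unless given a frozen
    stack), then fit the SVM on encoded positives vs negatives."""
    t_matrix = build_feature_matrix(pos_pairs, sd, sm, role="T")
    if layers is None:
        ae_cfg = replace(cfg.ae, seed=derive_seed(cfg.seed, "ae"))
        layers = greedy_pretrain(t_matrix.values, ae_cfg)
    encoded_pos = stack_encode(layers, t_matrix.values)
    nt_matrix = build_feature_matrix(neg_pairs, sd, sm, role="NT")
    encoded_neg = stack_encode(layers, nt_matrix.values)
    model = train_svm(
        encoded_pos, encoded_neg, C=cfg.svm_c, seed=cfg.seed, kernel=cfg.svm_kernel
    )
    return FittedPredictor(layers=layers, model=model, sd=sd, sm=sm)


def run_pipeline(
    dataset: Dataset,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[RankedPredictions, dict]:
    """Run the three stages end to end and rank every candidate cell.

    Returns the ranked predictions and a self-describing report; if
    ``outdir`` is given, writes ``predictions.tsv``, ``model.json`` and
    ``report.json`` there.
    """
    cfg = cfg or PipelineConfig()
    assoc = dataset.associations
    sd, sm, _ = compute_similarities(assoc, dataset.dags, dataset.fs, cfg)
    positives = assoc.positive_pairs()
    negatives = sample_negatives(assoc, len(positives), seed=derive_seed(cfg.seed, "neg"))
    predictor = fit_predictor(sd, sm, positives, negatives, cfg)
    candidates = candidate_pairs(assoc)
    scores = predictor.score_pairs(candidates)
    predictions = rank_candidates(scores, candidates)
    report = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "nd": assoc.nd,
        "nm": assoc.nm,
        "n_positives": len(positives),
        "n_candidates": len(candidates),
        "encoder_sizes": [layer.n_hidden for layer in predictor.layers],
        "seeds": {
            "base": cfg.seed,
            "negative_sampling": derive_seed(cfg.seed, "neg"),
            "autoencoder": derive_seed(cfg.seed, "ae"),
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_predictions(predictions, outdir / "predictions.tsv")
        save_stack(outdir / "model.json", predictor.layers, cfg.ae)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return predictions, report
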
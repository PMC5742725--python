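"""Disease/miRNA similarity computations.

Three ingredients feed the integrated similarity matrices used downstream:

1. **Semantic similarity, model 1** — each disease is a MeSH-style DAG of
   ancestor terms; an ancestor's contribution decays by the semantic
   contribution factor ``delta`` per edge along the best (shortest) path to
   the target, and two diseases are similar in proportion to the
   contributions of the terms their DAGs share.
2. **Semantic similarity, model 2** — an information-content variant in
   which a term's contribution is ``-log`` of the fraction of disease DAGs
   containing it, so rare (specific) terms weigh more.
3. **Gaussian interaction-profile (GIP) kernels** — an RBF kernel on the
   binary rows (diseases) or columns (miRNAs) of the association matrix,
   with the bandwidth normalised by the mean squared profile norm.

The integrated disease matrix SD uses the averaged semantic similarity
where both diseases have a DAG and the GIP kernel otherwise; the miRNA
matrix SM does the same with functional similarity versus its kernel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = [
    "SemanticContributionTable",
    "KernelBandwidth",
    "semantic_contributions_m1",
    "semantic_similarity_m1",
    "specificity_contributions_m2",
    "semantic_value_m2",
    "semantic_similarity_m2",
    "disease_semantic_matrix",
    "gip_kernel",
    "integrated_similarity",
]


@dataclass(frozen=True)
class SemanticContributionTable:
    """Per-term semantic contributions to one disease (model 1)."""

    target: str
    contributions: Mapping[str, float]
    delta: float
    semantic_value: float


@dataclass(frozen=True)
class KernelBandwidth:
    """Raw and profile-normalised GIP bandwidth."""

    alpha_prime: float
    alpha: float


def semantic_contributions_m1(dag: DiseaseDAG, delta: float = 0.5) -> SemanticContributionTable:
    """Model-1 contributions: 1 at the target, then max of ``delta`` times a
    child's contribution for every ancestor term."""
    if not 0.0 < delta <= 1.0:
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    memo: dict[str, float] = {dag.target: 1.0}

    def contribution(term: str) -> float:
        if term in memo:
            return memo[term]
        kids = dag.children(term)
        # every non-target node reaches the target, so kids is non-empty
        memo[term] = max(delta * contribution(c) for c in kids)
        return memo[term]

    for term in dag.nodes:
        contribution(term)
    return SemanticContributionTable(
        target=dag.target,
        contributions=dict(memo),
        delta=delta,
        semantic_value=float(sum(memo.values())),
    )


def semantic_similarity_m1(ti: SemanticContributionTable, tj: SemanticContributionTable) -> float:
    """Shared-term contribution overlap normalised by the two semantic values."""
    if ti.delta != tj.delta:
        raise ValueError("contribution tables built with different delta")
    shared = ti.contributions.keys() & tj.contributions.keys()
    numerator = sum(ti.contributions[k] + tj.contributions[k] for k in shared)
    return float(numerator / (ti.semantic_value + tj.semantic_value))


def specificity_contributions_m2(dags: Mapping[str, DiseaseDAG]) -> dict[str, float]:
    """Model-2 contribution of each term: -ln(fraction of DAGs containing it)."""
    if not dags:
        raise ValueError("at least one DAG required")
    n = len(dags)
    counts: dict[str, int] = {}
    for dag in dags.values():
        for term in dag.nodes:
            counts[term] = counts.get(term, 0) + 1
    return {term: -math.log(c / n) for term, c in counts.items()}


def semantic_value_m2(dag: DiseaseDAG, spec: Mapping[str, float]) -> float:
    missing = dag.nodes - spec.keys()
    if missing:
        raise ValueError(f"specificity table missing terms {sorted(missing)}")
    return float(sum(spec[d] for d in dag.nodes))


def semantic_similarity_m2(
    dag_i: DiseaseDAG, dag_j: DiseaseDAG, spec: Mapping[str, float]
) -> float:
    """Model-2 similarity: shared specificity mass over total specificity."""
    d2i = semantic_value_m2(dag_i, spec)
    d2j = semantic_value_m2(dag_j, spec)
    if d2i + d2j == 0.0:
        warnings.warn(
            f"all terms of {dag_i.target!r} and {dag_j.target!r} are universal; "
            "model-2 similarity set to 0",
            stacklevel=2,
        )
        return 0.0
    shared = dag_i.nodes & dag_j.nodes
    numerator = sum(2.0 * spec[k] for k in shared)
    return float(numerator / (d2i + d2j))


def disease_semantic_matrix(
    dags: Mapping[str, DiseaseDAG], delta: float = 0.5
) -> SimilarityMatrix:
    """Average of model-1 and model-2 semantic similarity over all DAG pairs."""
    labels = tuple(sorted(dags))
    n = len(labels)
    tables = {d: semantic_contributions_m1(dags[d], delta) for d in labels}
    spec = specificity_contributions_m2(dags)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ss1 = semantic_similarity_m1(tables[labels[i]], tables[labels[j]])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ss2 = semantic_similarity_m2(dags[labels[i]], dags[labels[j]], spec)
            values[i, j] = values[j, i] = 0.5 * (ss1 + ss2)
    return SimilarityMatrix(labels, values)


def gip_kernel(
    assoc: AssociationMatrix, axis: str, alpha_prime: float = 1.0
) -> tuple[SimilarityMatrix, KernelBandwidth]:
    """Gaussian kernel on interaction profiles.

    ``axis`` selects disease profiles (rows of A) or miRNA profiles
    (columns).  The bandwidth is ``alpha_prime`` divided by the mean squared
    profile norm, i.e. the average number of interactions per entity.
    """
    if alpha_prime <= 0:
        raise ValueError("alpha_prime must be positive")
    if axis == "diseases":
        profiles, labels = assoc.values, assoc.disease_labels
    elif axis == "mirnas":
        profiles, labels = assoc.values.T, assoc.mirna_labels
    else:
        raise ValueError(f"axis must be 'diseases' or 'mirnas', got {axis!r}")
    sq_norms = (profiles * profiles).sum(axis=1)
    mean_sq = float(sq_norms.mean())
    if mean_sq == 0.0:
        raise ValueError("all-zero association matrix: kernel bandwidth undefined")
    alpha = alpha_prime / mean_sq
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.clip(sq_dist, 0.0, None, out=sq_dist)
    kernel = np.exp(-alpha * sq_dist)
    np.fill_diagonal(kernel, 1.0)
    kernel = (kernel + kernel.T) / 2.0
    return SimilarityMatrix(labels, kernel), KernelBandwidth(alpha_prime, alpha)


def integrated_similarity(
    semantic: SimilarityMatrix | None,
    kernel: SimilarityMatrix,
    covered: Iterable[str] | None = None,
    mode: str = "dag",
) -> SimilarityMatrix:
    """Entry-wise choice between semantic/functional similarity and kernel.

    A pair takes its semantic value when both members are ``covered``
    (by default: appear in the semantic matrix), and the kernel value
    otherwise.  ``mode='positive'`` additionally falls back to the kernel
    where the semantic entry is exactly zero.
    """
    if mode not in ("dag", "positive"):
        raise ValueError(f"mode must be 'dag' or 'positive', got {mode!r}")
    if semantic is None:
        return SimilarityMatrix(kernel.labels, kernel.values.copy())
    if covered is None:
        covered = semantic.labels
    covered = set(covered)
    unknown = covered - set(kernel.labels)
    if unknown:
        raise ValueError(f"label mismatch: {sorted(unknown)} absent from kernel matrix")
    missing = covered - set(semantic.labels)
    if missing:
        raise ValueError(f"label mismatch: {sorted(missing)} absent from semantic matrix")
    out = kernel.values.copy()
    kidx = [i for i, lab in enumerate(kernel.labels) if lab in covered]
    sidx = [semantic.index(kernel.labels[i]) for i in kidx]
    block = semantic.values[np.ix_(sidx, sidx)]
    if mode == "positive":
        block = np.where(block > 0.0, block, out[np.ix_(kidx, kidx)])
    out[np.ix_(kidx, kidx)] = block
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(kernel.labels, out)
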
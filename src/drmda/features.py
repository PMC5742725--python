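"""Feature assembly for disease-miRNA pairs.

A pair (d(i), m(j)) is described by stacking column i of the integrated
disease similarity SD on top of column j of the integrated miRNA similarity
SM, so every feature vector has nd + nm rows and entries in [0, 1].  The
matrix of known associations is T; sampled negatives form NT; all unknown
cells form AT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import AssociationMatrix, SimilarityMatrix

__all__ = ["FeatureMatrix", "build_feature_matrix", "sample_negatives", "candidate_pairs"]


@dataclass
class FeatureMatrix:
    """Columns of stacked SD/SM similarity profiles, one per pair."""

    pairs: list[tuple[str, str]]
    values: np.ndarray  # (nd + nm, n_pairs)
    role: str = "T"

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.pairs):
            raise ValueError("feature matrix shape does not match pair list")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_feature_matrix(
    pairs: Sequence[tuple[str, str]],
    sd: SimilarityMatrix,
    sm: SimilarityMatrix,
    role: str = "T",
) -> FeatureMatrix:
    """Stack SD column of the disease over SM column of the miRNA per pair."""
    nd, nm = len(sd.labels), len(sm.labels)
    values = np.empty((nd + nm, len(pairs)))
    d_index = {lab: i for i, lab in enumerate(sd.labels)}
    m_index = {lab: j for j, lab in enumerate(sm.labels)}
    try:
        di = np.array([d_index[d] for d, _ in pairs], dtype=int)
        mi = np.array([m_index[m] for _, m in pairs], dtype=int)
    except KeyError as exc:
        bad = next((p for p in pairs if p[0] not in d_index or p[1] not in m_index))
        raise ValueError(f"unknown label in pair {bad!r}") from exc
    if pairs:
        values[:nd, :] = sd.values[:, di]
        values[nd:, :] = sm.values[:, mi]
    return FeatureMatrix(list(pairs), values, role)


def sample_negatives(
    assoc: AssociationMatrix,
    n: int,
    seed: int,
    exclude: Iterable[tuple[str, str]] = (),
) -> list[tuple[str, str]]:
    """Sample ``n`` distinct unknown cells uniformly without replacement.

    ``exclude`` removes cells (e.g. a held-out positive) from the sampling
    universe on top of the known positives.
    """
    excluded = set(exclude)
    zeros = [p for p in assoc.zero_pairs() if p not in excluded]
    if n > len(zeros):
        raise ValueError(f"requested {n} negatives but only {len(zeros)} unknown cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(zeros), size=n, replace=False)
    return [zeros[i] for i in idx]


def candidate_pairs(assoc: AssociationMatrix) -> list[tuple[str, str]]:
    """All unknown cells, row-major over (disease, miRNA) label order."""
    return assoc.zero_pairs()
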
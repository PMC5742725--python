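"""Labelled-matrix containers and plain-text I/O.

All on-disk formats are TSV, UTF-8:

* **associations** — one ``disease<TAB>miRNA`` pair per line; extra columns
  (PMIDs, free-text descriptions in database dumps) are ignored.
* **disease DAGs** — ``target<TAB>parent<TAB>child`` edge rows; a row with an
  empty parent field declares a root-only graph for its target.
* **similarity matrix** — square matrix with a header row and a label column.
* **predictions** — ``disease  miRNA  score  rank`` with a header line.

Labels are whitespace-trimmed and case-sensitive.  Matrices are laid out over
lexicographically sorted labels so repeated runs produce identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "AssociationMatrix",
    "DiseaseDAG",
    "SimilarityMatrix",
    "RankedPredictions",
    "Dataset",
    "read_associations",
    "write_associations",
    "read_dags",
    "write_dags",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_predictions",
    "write_predictions",
]

#: symmetry tolerance for in-memory similarity matrices
SYMMETRY_TOL = 1e-10
#: asymmetry beyond this is an error when reading; below it we average
READ_SYMMETRY_TOL = 1e-6
#: tolerated numeric slop outside [0, 1] on file input
RANGE_TOL = 1e-9


class FormatError(ValueError):
    """An input file violates its dialect."""


def _check_labels(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels")
    if any(not str(lab).strip() for lab in labels):
        raise ValueError(f"empty {what} label")


@dataclass
class AssociationMatrix:
    """Binary disease x miRNA association matrix.

    ``values[i, j] == 1`` iff disease ``disease_labels[i]`` is associated
    with miRNA ``mirna_labels[j]``.
    """

    disease_labels: tuple[str, ...]
    mirna_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.disease_labels = tuple(self.disease_labels)
        self.mirna_labels = tuple(self.mirna_labels)
        _check_labels(self.disease_labels, "disease")
        _check_labels(self.mirna_labels, "miRNA")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.disease_labels), len(self.mirna_labels)):
            raise ValueError("association matrix shape does not match labels")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def nd(self) -> int:
        return len(self.disease_labels)

    @property
    def nm(self) -> int:
        return len(self.mirna_labels)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def disease_index(self, label: str) -> int:
        try:
            return self.disease_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown disease label {label!r}") from None

    def mirna_index(self, label: str) -> int:
        try:
            return self.mirna_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown miRNA label {label!r}") from None

    def positive_pairs(self) -> list[tuple[str, str]]:
        """Known associations in row-major (disease, miRNA) label order."""
        ii, jj = np.nonzero(self.values)
        return [(self.disease_labels[i], self.mirna_labels[j]) for i, j in zip(ii, jj)]

    def zero_pairs(self) -> list[tuple[str, str]]:
        """Unknown cells in row-major (disease, miRNA) label order."""
        ii, jj = np.nonzero(self.values == 0)
        return [(self.disease_labels[i], self.mirna_labels[j]) for i, j in zip(ii, jj)]

    def without(self, pairs: Iterable[tuple[str, str]]) -> "AssociationMatrix":
        """Copy with the given positive cells zeroed (for held-out folds)."""
        vals = self.values.copy()
        for d, m in pairs:
            vals[self.disease_index(d), self.mirna_index(m)] = 0.0
        return AssociationMatrix(self.disease_labels, self.mirna_labels, vals)


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease term plus its ancestor graph.

    ``nodes`` contains the target and every ancestor; ``edges`` are directed
    parent -> child pairs, the target being the most derived term.  Every
    non-target node must have a directed path down to the target.
    """

    target: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        if self.target not in self.nodes:
            raise ValueError(f"target {self.target!r} missing from its own DAG")
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise ValueError(f"edge ({p!r}, {c!r}) uses a term outside the DAG of {self.target!r}")
        graph = nx.DiGraph()
        graph.add_nodes_from(self.nodes)
        graph.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError(f"cycle detected in DAG for {self.target!r}")
        reachable = nx.ancestors(graph, self.target)
        stray = self.nodes - reachable - {self.target}
        if stray:
            raise ValueError(
                f"terms {sorted(stray)} have no edge chain reaching {self.target!r}"
            )

    def children(self, term: str) -> set[str]:
        return {c for p, c in self.edges if p == term}


@dataclass
class SimilarityMatrix:
    """Labelled symmetric square matrix with entries in [0, 1], unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        _check_labels(self.labels, "similarity")
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError("similarity matrix is not square over its labels")
        if np.abs(vals - vals.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if vals.min(initial=1.0) < -RANGE_TOL or vals.max(initial=0.0) > 1.0 + RANGE_TOL:
            raise ValueError("similarity entries outside [0, 1]")
        vals = np.clip(vals, 0.0, 1.0)
        if n and np.abs(np.diag(vals) - 1.0).max() > SYMMETRY_TOL:
            raise ValueError("similarity diagonal must be 1")
        self.values = vals

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None


@dataclass
class RankedPredictions:
    """Per-disease ranked candidate scores.

    Rows are ``(disease, miRNA, score, rank)``; within each disease ranks run
    1..k in order of non-increasing score.
    """

    rows: list[tuple[str, str, float, int]]

    def __post_init__(self) -> None:
        per_disease: dict[str, list[tuple[float, int]]] = {}
        for d, m, s, r in self.rows:
            per_disease.setdefault(d, []).append((float(s), int(r)))
        for d, entries in per_disease.items():
            ranks = [r for _, r in entries]
            if ranks != list(range(1, len(entries) + 1)):
                raise ValueError(f"ranks for disease {d!r} are not 1..k in order")
            scores = [s for s, _ in entries]
            if any(a < b for a, b in zip(scores, scores[1:])):
                raise ValueError(f"scores for disease {d!r} are not non-increasing")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[tuple[str, str, float, int]]:
        return iter(self.rows)


@dataclass
class Dataset:
    """The three inputs of the predictor, bundled."""

    associations: AssociationMatrix
    dags: Mapping[str, DiseaseDAG] = field(default_factory=dict)
    fs: SimilarityMatrix | None = None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a disease/miRNA pair list into a binary matrix.

    Duplicate pairs collapse to a single 1; labels are sorted
    lexicographically.  Columns beyond the first two are ignored.
    """
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected at least 2 tab-separated fields")
            disease, mirna = fields[0].strip(), fields[1].strip()
            if not disease or not mirna:
                raise FormatError(f"{path}: line {lineno}: empty disease or miRNA label")
            pairs.add((disease, mirna))
    if not pairs:
        raise FormatError(f"{path}: no associations")
    diseases = tuple(sorted({d for d, _ in pairs}))
    mirnas = tuple(sorted({m for _, m in pairs}))
    if len(diseases) < 2 or len(mirnas) < 2:
        raise FormatError(f"{path}: need at least 2 distinct diseases and 2 distinct miRNAs")
    values = np.zeros((len(diseases), len(mirnas)))
    drow = {d: i for i, d in enumerate(diseases)}
    mcol = {m: j for j, m in enumerate(mirnas)}
    for d, m in pairs:
        values[drow[d], mcol[m]] = 1.0
    return AssociationMatrix(diseases, mirnas, values)


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for d, m in assoc.positive_pairs():
            handle.write(f"{d}\t{m}\n")


def read_dags(path: str | Path) -> dict[str, DiseaseDAG]:
    """Read per-disease DAGs from a (target, parent, child) edge list."""
    edges: dict[str, set[tuple[str, str]]] = {}
    roots_only: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected target, parent, child")
            target, parent, child = (f.strip() for f in fields[:3])
            if not target or not child:
                raise FormatError(f"{path}: line {lineno}: empty target or child term")
            if parent:
                edges.setdefault(target, set()).add((parent, child))
            else:
                roots_only.setdefault(target, set()).add(child)
    dags: dict[str, DiseaseDAG] = {}
    for target in sorted(set(edges) | set(roots_only)):
        target_edges = edges.get(target, set())
        nodes = {target} | roots_only.get(target, set())
        for p, c in target_edges:
            nodes |= {p, c}
        try:
            dags[target] = DiseaseDAG(target, frozenset(nodes), frozenset(target_edges))
        except ValueError as exc:
            raise FormatError(f"{path}: invalid DAG for {target!r}: {exc}") from exc
    return dags


def write_dags(dags: Mapping[str, DiseaseDAG], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for target in sorted(dags):
            dag = dags[target]
            if not dag.edges:
                handle.write(f"{target}\t\t{target}\n")
            else:
                for p, c in sorted(dag.edges):
                    handle.write(f"{target}\t{p}\t{c}\n")


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a labelled square similarity matrix.

    Mild asymmetry (<= 1e-6) is repaired by averaging with the transpose;
    the diagonal is forced to 1.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels = tuple(str(lab).strip() for lab in frame.index)
    columns = tuple(str(lab).strip() for lab in frame.columns)
    if frame.shape[0] != frame.shape[1]:
        raise FormatError(f"{path}: matrix is not square ({frame.shape[0]}x{frame.shape[1]})")
    if labels != columns:
        raise FormatError(f"{path}: row labels do not match column labels")
    values = frame.to_numpy(dtype=float)
    if values.min(initial=1.0) < -RANGE_TOL or values.max(initial=0.0) > 1.0 + RANGE_TOL:
        raise FormatError(f"{path}: similarity entry outside [0, 1]")
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > READ_SYMMETRY_TOL:
        raise FormatError(f"{path}: asymmetry {asym:g} exceeds {READ_SYMMETRY_TOL:g}")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels, np.clip(values, 0.0, 1.0))


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(sim.values, index=list(sim.labels), columns=list(sim.labels))
    frame.to_csv(path, sep="\t", float_format="%.12g")


def write_predictions(preds: RankedPredictions, path: str | Path) -> None:
    """Write predictions as TSV, scores with 6 significant digits."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("disease\tmiRNA\tscore\trank\n")
        for d, m, s, r in preds:
            handle.write(f"{d}\t{m}\t{s:.6g}\t{r}\n")


def read_predictions(path: str | Path) -> RankedPredictions:
    rows: list[tuple[str, str, float, int]] = []
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("disease\tmiRNA"):
            raise FormatError(f"{path}: missing predictions header")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 fields")
            d, m, s, r = fields
            rows.append((d, m, float(s), int(r)))
    return RankedPredictions(rows)
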
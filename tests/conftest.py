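"""Shared fixtures: hand-built DAGs, a small simulated dataset, random-DAG helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from drmda.fixtures import FixtureConfig, simulate_dataset
from drmda.io import DiseaseDAG


def make_dag(target: str, edges: list[tuple[str, str]], extra_nodes: set[str] | None = None) -> DiseaseDAG:
    nodes = {target} | (extra_nodes or set())
    for p, c in edges:
        nodes |= {p, c}
    return DiseaseDAG(target, frozenset(nodes), frozenset(edges))


@pytest.fixture
def chain_dag() -> DiseaseDAG:
    """p -> D."""
    return make_dag("D", [("p", "D")])


@pytest.fixture
def diamond_dag() -> DiseaseDAG:
    """g -> p -> D and g -> D."""
    return make_dag("D", [("g", "p"), ("p", "D"), ("g", "D")])


@pytest.fixture
def shared_parent_trio() -> dict[str, DiseaseDAG]:
    """d1 and d2 share parent p; d3 is a bare root.  p sits in 2 of 3 DAGs."""
    return {
        "d1": make_dag("d1", [("p", "d1")]),
        "d2": make_dag("d2", [("p", "d2")]),
        "d3": make_dag("d3", []),
    }


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted dataset reused across protocol tests."""
    return simulate_dataset(FixtureConfig(nd=8, nm=10, density=0.2, noise=0.0, seed=5))


def random_dag(rng: np.random.Generator, target: str, pool: list[str], max_extra: int = 9) -> DiseaseDAG:
    """Random DAG whose non-target terms come from a shared pool.

    Terms are added one at a time as parents of already-present nodes, so
    acyclicity and reachability of the target hold by construction.
    """
    n_extra = int(rng.integers(0, max_extra + 1))
    terms = list(rng.choice(pool, size=min(n_extra, len(pool)), replace=False))
    present = [target]
    edges: set[tuple[str, str]] = set()
    for term in terms:
        n_children = int(rng.integers(1, min(2, len(present)) + 1))
        kids = rng.choice(len(present), size=n_children, replace=False)
        for k in kids:
            edges.add((term, present[int(k)]))
        present.append(term)
    return make_dag(target, sorted(edges), extra_nodes={target})


# ---------------------------------------------------------------------------
# independent brute-force oracles for the semantic similarity models
# ---------------------------------------------------------------------------


def oracle_contributions_m1(dag: DiseaseDAG, delta: float) -> dict[str, float]:
    """delta ** (shortest path length to the target), by full path enumeration."""

    def path_lengths(term: str) -> list[int]:
        if term == dag.target:
            return [0]
        out: list[int] = []
        for child in dag.children(term):
            out.extend(length + 1 for length in path_lengths(child))
        return out

    return {term: delta ** min(path_lengths(term)) for term in dag.nodes}


def oracle_ss1(dag_i: DiseaseDAG, dag_j: DiseaseDAG, delta: float) -> float:
    ddi = oracle_contributions_m1(dag_i, delta)
    ddj = oracle_contributions_m1(dag_j, delta)
    num = 0.0
    for term in set(ddi) & set(ddj):
        num += ddi[term] + ddj[term]
    return num / (sum(ddi.values()) + sum(ddj.values()))


def oracle_ss2(dags: dict[str, DiseaseDAG], a: str, b: str) -> float:
    n = len(dags)
    counts: dict[str, int] = {}
    for dag in dags.values():
        for term in dag.nodes:
            counts[term] = counts.get(term, 0) + 1
    spec = {term: -math.log(c / n) for term, c in counts.items()}
    d2a = sum(spec[t] for t in dags[a].nodes)
    d2b = sum(spec[t] for t in dags[b].nodes)
    if d2a + d2b == 0.0:
        return 0.0
    num = sum(2.0 * spec[t] for t in dags[a].nodes & dags[b].nodes)
    return num / (d2a + d2b)
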
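"""Synthetic datasets with the structure the predictor assumes.

The generator plants a low-rank logistic association model in which similar
diseases (sharing DAG ancestry) and similar miRNAs (sharing a functional
cluster) have correlated interaction profiles — the "guilt by association"
structure the method exploits:

* diseases are leaves of a random forest of shared ancestor terms, so DAG
  overlap induces graded semantic similarity;
* each forest node carries a latent vector drifting from its parent; a
  disease inherits its attachment node's vector plus idiosyncratic noise,
  and also a scalar propensity emulating the heavy hub structure of curated
  association databases;
* miRNAs draw latent vectors around cluster centres plus a propensity; the
  functional-similarity matrix FS is an affine map of latent cosine
  similarity into [0, 1];
* the probability of association (i, j) is a logistic link in the latent
  inner product plus both propensities, shifted so the mean probability
  matches the target density, then sampled with common random numbers keyed
  by the disease latent (identical latents give identical rows) and
  optionally corrupted by independent bit flips.

Every generated entity keeps at least one association so a write/read round
trip preserves the label sets.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.special import expit

from .io import AssociationMatrix, Dataset, DiseaseDAG, SimilarityMatrix

__all__ = ["FixtureConfig", "SimulatedDataset", "simulate_dataset", "sample_association_rows"]

#: logistic link temperature — small values give a sharp, nearly
#: deterministic planted signal
LINK_TEMPERATURE = 0.25
#: standard deviation of per-entity propensities (hub strength)
PROPENSITY_SD = 0.8
#: latent drift scales down the ancestor forest and within miRNA clusters
ANCESTOR_DRIFT = 0.45
LEAF_DRIFT = 0.35
CLUSTER_DRIFT = 0.45


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the planted-association generator."""

    nd: int
    nm: int
    dag_depth: int = 4
    n_shared_ancestors: int = 3
    latent_rank: int = 3
    density: float = 0.15
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nd < 4 or self.nm < 4:
            raise ValueError("nd and nm must be at least 4")
        if not 0.0 < self.density < 0.5:
            raise ValueError("density must be in (0, 0.5)")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be at least 1")
        if self.dag_depth < 2:
            raise ValueError("dag_depth must be at least 2")
        if self.n_shared_ancestors < 1:
            raise ValueError("need at least one shared ancestor root")


@dataclass
class SimulatedDataset(Dataset):
    """Dataset plus the planted ground truth used to generate it."""

    planted_probability: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    disease_latents: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    mirna_latents: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    config: FixtureConfig | None = None

    def __iter__(self) -> Iterator:
        """Unpack as the (associations, dags, fs) input triple."""
        return iter((self.associations, self.dags, self.fs))


def _latent_key(latent_row: np.ndarray) -> int:
    return zlib.crc32(np.ascontiguousarray(np.round(latent_row, 10)).tobytes())


def sample_association_rows(
    probs: np.ndarray, disease_latents: np.ndarray, seed: int
) -> np.ndarray:
    """Bernoulli-sample rows with uniforms keyed by the disease latent.

    Two diseases with identical latent vectors receive identical uniform
    draws, so equal probability rows sample to equal association rows.
    """
    probs = np.asarray(probs, dtype=float)
    out = np.zeros_like(probs)
    for i in range(probs.shape[0]):
        key = _latent_key(disease_latents[i])
        uniforms = np.random.default_rng(np.random.SeedSequence([seed, key])).random(
            probs.shape[1]
        )
        out[i] = (uniforms < probs[i]).astype(float)
    return out


def _calibrate_shift(scores: np.ndarray, density: float, temperature: float) -> float:
    """Bisection for the logistic shift giving mean probability = density."""
    lo = float(scores.min()) - 40.0 * temperature
    hi = float(scores.max()) + 40.0 * temperature
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(expit((scores - mid) / temperature).mean()) > density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_dataset(cfg: FixtureConfig) -> SimulatedDataset:
    """Generate (associations, DAG forest, FS) with planted structure."""
    rng = np.random.default_rng(cfg.seed)
    rank = cfg.latent_rank

    # --- ancestor forest -------------------------------------------------
    roots = [f"anc{r}" for r in range(cfg.n_shared_ancestors)]
    term_latent: dict[str, np.ndarray] = {}
    term_depth: dict[str, int] = {}
    term_parent: dict[str, str | None] = {}
    terms_per_root: dict[str, list[str]] = {}
    for root in roots:
        term_latent[root] = rng.normal(0.0, 1.0, rank)
        term_depth[root] = 1
        term_parent[root] = None
        terms_per_root[root] = [root]
        n_internal = max(1, cfg.nd // (2 * cfg.n_shared_ancestors))
        for t in range(n_internal):
            eligible = [u for u in terms_per_root[root] if term_depth[u] < cfg.dag_depth - 1]
            if not eligible:
                break
            parent = eligible[rng.integers(len(eligible))]
            name = f"{root}.{t}"
            term_latent[name] = term_latent[parent] + rng.normal(0.0, ANCESTOR_DRIFT, rank)
            term_depth[name] = term_depth[parent] + 1
            term_parent[name] = parent
            terms_per_root[root].append(name)

    # --- diseases ---------------------------------------------------------
    width = len(str(cfg.nd - 1))
    disease_labels = tuple(f"d{i:0{width}d}" for i in range(cfg.nd))
    dags: dict[str, DiseaseDAG] = {}
    disease_latents = np.empty((cfg.nd, rank + 2))
    for i, label in enumerate(disease_labels):
        root = roots[rng.integers(len(roots))]
        attach = terms_per_root[root][rng.integers(len(terms_per_root[root]))]
        path = [attach]
        while term_parent[path[-1]] is not None:
            path.append(term_parent[path[-1]])
        path.reverse()  # root ... attach
        nodes = frozenset(path) | {label}
        edges = frozenset(zip(path, path[1:])) | {(attach, label)}
        dags[label] = DiseaseDAG(label, nodes, edges)
        core = term_latent[attach] + rng.normal(0.0, LEAF_DRIFT, rank)
        propensity = rng.normal(0.0, PROPENSITY_SD)
        disease_latents[i] = np.concatenate([core, [propensity, 1.0]])

    # --- miRNAs -----------------------------------------------------------
    width_m = len(str(cfg.nm - 1))
    mirna_labels = tuple(f"m{j:0{width_m}d}" for j in range(cfg.nm))
    centres = rng.normal(0.0, 1.0, (cfg.n_shared_ancestors, rank))
    mirna_latents = np.empty((cfg.nm, rank + 2))
    for j in range(cfg.nm):
        centre = centres[rng.integers(len(centres))]
        core = centre + rng.normal(0.0, CLUSTER_DRIFT, rank)
        propensity = rng.normal(0.0, PROPENSITY_SD)
        mirna_latents[j] = np.concatenate([core / np.sqrt(rank), [1.0, propensity]])

    # --- planted probabilities and sampling -------------------------------
    scores = disease_latents @ mirna_latents.T
    shift = _calibrate_shift(scores, cfg.density, LINK_TEMPERATURE)
    probs = expit((scores - shift) / LINK_TEMPERATURE)
    values = sample_association_rows(probs, disease_latents, cfg.seed)
    if cfg.noise > 0.0:
        flips = rng.random((cfg.nd, cfg.nm)) < cfg.noise
        values = np.where(flips, 1.0 - values, values)
    # keep every entity on the association list so labels survive round trips
    for i in range(cfg.nd):
        if values[i].sum() == 0.0:
            values[i, int(np.argmax(probs[i]))] = 1.0
    for j in range(cfg.nm):
        if values[:, j].sum() == 0.0:
            values[int(np.argmax(probs[:, j])), j] = 1.0

    realized = float(values.mean())
    # 20% relative band plus three standard errors of the realised mean, so
    # small matrices are not rejected for ordinary binomial fluctuation
    sampling_allowance = 3.0 * np.sqrt(cfg.density * (1.0 - cfg.density) / (cfg.nd * cfg.nm))
    if abs(realized - cfg.density) > 0.20 * cfg.density + sampling_allowance:
        raise ValueError(
            f"infeasible density: realised {realized:.4f} vs target {cfg.density:.4f}"
        )

    # --- functional similarity --------------------------------------------
    norms = np.linalg.norm(mirna_latents, axis=1)
    cosine = (mirna_latents @ mirna_latents.T) / np.outer(norms, norms)
    fs_values = (1.0 + cosine) / 2.0
    fs_values = (fs_values + fs_values.T) / 2.0
    np.fill_diagonal(fs_values, 1.0)
    fs = SimilarityMatrix(mirna_labels, np.clip(fs_values, 0.0, 1.0))

    assoc = AssociationMatrix(disease_labels, mirna_labels, values)
    return SimulatedDataset(
        associations=assoc,
        dags=dags,
        fs=fs,
        planted_probability=probs,
        disease_latents=disease_latents,
        mirna_latents=mirna_latents,
        config=cfg,
    )
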
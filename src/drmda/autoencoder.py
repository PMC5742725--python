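"""Stacked sparse auto-encoder with greedy layer-wise pretraining.

Each layer is a sigmoid auto-encoder trained to reconstruct its input under
three cost terms: mean squared reconstruction error, an L2 weight-decay
penalty ``delta_wd/2 * sum(W^2)``, and a sparsity penalty ``beta`` times the
sum over hidden units of the KL divergence between a Bernoulli target rate
``rho`` and the unit's mean activation over the sample set.  Layers are
trained one at a time, full batch, by L-BFGS from a seeded uniform
initialisation; each subsequent layer sees the previous layer's encodings.
Training is unsupervised throughout: there is no supervised fine-tuning, and
once trained the encoder stack is frozen for scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "AutoencoderLayer",
    "TrainingConfig",
    "SparsityStats",
    "LayerGradients",
    "kl_divergence",
    "sparse_cost_and_grad",
    "train_layer",
    "greedy_pretrain",
    "stack_encode",
    "resolve_layer_sizes",
    "save_stack",
    "load_stack",
]

_RHO_HAT_CLIP = 1e-8


@dataclass
class AutoencoderLayer:
    """One sigmoid encoder/decoder pair with untied weights."""

    W_enc: np.ndarray  # (n_hidden, n_in)
    b_enc: np.ndarray  # (n_hidden,)
    W_dec: np.ndarray  # (n_in, n_hidden)
    b_dec: np.ndarray  # (n_in,)

    def __post_init__(self) -> None:
        h, d = self.W_enc.shape
        if self.b_enc.shape != (h,) or self.W_dec.shape != (d, h) or self.b_dec.shape != (d,):
            raise ValueError("inconsistent layer shapes")
        for arr in (self.W_enc, self.b_enc, self.W_dec, self.b_dec):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite layer parameters")

    @property
    def n_in(self) -> int:
        return self.W_enc.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_enc.shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        if X.shape[0] != self.n_in:
            raise ValueError(f"expected {self.n_in} input rows, got {X.shape[0]}")
        return expit(self.W_enc @ X + self.b_enc[:, None])

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        hidden = self.encode(X)
        return expit(self.W_dec @ hidden + self.b_dec[:, None])


class LayerGradients(NamedTuple):
    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray


@dataclass(frozen=True)
class SparsityStats:
    """Mean hidden activations over a sample set."""

    rho_hat: np.ndarray
    n2: int


@dataclass
class TrainingConfig:
    """Sparse auto-encoder hyperparameters.

    ``layer_sizes=None`` resolves to ``[n_in, 250, 80]``, the stack used on
    the full-scale association data; smaller inputs must pass explicit
    sizes.  ``beta=5`` and ``rho=0.05`` are the standard sparsity settings;
    ``delta_wd`` is the L2 weight-decay coefficient applied to encoder (and,
    unless ``regularize_decoder`` is off, decoder) weights but never biases.
    """

    layer_sizes: Sequence[int] | None = None
    delta_wd: float = 1e-4
    beta: float = 5.0
    rho: float = 0.05
    max_iter: int = 400
    seed: int = 0
    regularize_decoder: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must be in (0, 1)")
        if self.beta < 0 or self.delta_wd < 0:
            raise ValueError("beta and delta_wd must be non-negative")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")
        if self.layer_sizes is not None:
            sizes = [int(s) for s in self.layer_sizes]
            if any(s <= 0 for s in sizes) or len(sizes) < 2:
                raise ValueError("layer_sizes must list the input size and positive hidden sizes")
            if any(b >= a for a, b in zip(sizes, sizes[1:])):
                raise ValueError("layer sizes must decrease after the input layer")
            self.layer_sizes = sizes


def resolve_layer_sizes(cfg: TrainingConfig, n_in: int) -> list[int]:
    if cfg.layer_sizes is None:
        sizes = [n_in, 250, 80]
        if n_in <= 250:
            raise ValueError(
                f"default hidden sizes [250, 80] need an input wider than 250 rows, got {n_in}; "
                "pass explicit layer_sizes"
            )
        return sizes
    if cfg.layer_sizes[0] != n_in:
        raise ValueError(f"layer_sizes[0]={cfg.layer_sizes[0]} does not match input rows {n_in}")
    return list(cfg.layer_sizes)


def kl_divergence(rho: float, rho_hat: float) -> float:
    """KL divergence between Bernoulli(rho) and Bernoulli(rho_hat)."""
    if not (0.0 < rho < 1.0 and 0.0 < rho_hat < 1.0):
        raise ValueError("kl_divergence requires arguments in the open interval (0, 1)")
    return float(rho * np.log(rho / rho_hat) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat)))


def sparse_cost_and_grad(
    layer: AutoencoderLayer, X: np.ndarray, cfg: TrainingConfig
) -> tuple[float, LayerGradients]:
    """Full-batch sparse auto-encoder cost and its analytic gradients.

    Cost = mean over samples of half the squared reconstruction error
    + (delta_wd/2) * sum of squared weights
    + beta * sum_j KL(rho || rho_hat_j).
    """
    if X.shape[0] != layer.n_in:
        raise ValueError("sample matrix rows do not match layer input size")
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in sample matrix")
    n = X.shape[1]
    a2 = expit(layer.W_enc @ X + layer.b_enc[:, None])
    a3 = expit(layer.W_dec @ a2 + layer.b_dec[:, None])
    resid = a3 - X
    rec_cost = 0.5 * float(np.sum(resid * resid)) / n

    rho_hat = a2.mean(axis=1)
    clipped = np.clip(rho_hat, _RHO_HAT_CLIP, 1.0 - _RHO_HAT_CLIP)
    if np.any(clipped != rho_hat):
        warnings.warn("mean hidden activation saturated; clipped for the sparsity penalty", stacklevel=2)
    rho = cfg.rho
    kl_total = float(
        np.sum(rho * np.log(rho / clipped) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - clipped)))
    )

    wd_cost = 0.5 * cfg.delta_wd * float(np.sum(layer.W_enc**2))
    if cfg.regularize_decoder:
        wd_cost += 0.5 * cfg.delta_wd * float(np.sum(layer.W_dec**2))
    cost = rec_cost + wd_cost + cfg.beta * kl_total

    # backpropagation
    d3 = resid * a3 * (1.0 - a3) / n
    gW_dec = d3 @ a2.T
    if cfg.regularize_decoder:
        gW_dec += cfg.delta_wd * layer.W_dec
    gb_dec = d3.sum(axis=1)
    sparse_delta = cfg.beta * (-rho / clipped + (1.0 - rho) / (1.0 - clipped)) / n
    d2 = (layer.W_dec.T @ d3 + sparse_delta[:, None]) * a2 * (1.0 - a2)
    gW_enc = d2 @ X.T + cfg.delta_wd * layer.W_enc
    gb_enc = d2.sum(axis=1)
    return cost, LayerGradients(gW_enc, gb_enc, gW_dec, gb_dec)


def _pack(layer: AutoencoderLayer) -> np.ndarray:
    return np.concatenate(
        [layer.W_enc.ravel(), layer.b_enc, layer.W_dec.ravel(), layer.b_dec]
    )


def _unpack(theta: np.ndarray, n_in: int, n_hidden: int) -> AutoencoderLayer:
    sizes = [n_hidden * n_in, n_hidden, n_in * n_hidden, n_in]
    offsets = np.cumsum([0] + sizes)
    return AutoencoderLayer(
        W_enc=theta[offsets[0] : offsets[1]].reshape(n_hidden, n_in),
        b_enc=theta[offsets[1] : offsets[2]].copy(),
        W_dec=theta[offsets[2] : offsets[3]].reshape(n_in, n_hidden),
        b_dec=theta[offsets[3] : offsets[4]].copy(),
    )


def init_layer(n_in: int, n_hidden: int, seed: int) -> AutoencoderLayer:
    """Seeded uniform(-r, r) weight init with r = sqrt(6 / (n_in + n_hidden))."""
    rng = np.random.default_rng(seed)
    r = np.sqrt(6.0 / (n_in + n_hidden))
    return AutoencoderLayer(
        W_enc=rng.uniform(-r, r, (n_hidden, n_in)),
        b_enc=np.zeros(n_hidden),
        W_dec=rng.uniform(-r, r, (n_in, n_hidden)),
        b_dec=np.zeros(n_in),
    )


def train_layer(X: np.ndarray, n_hidden: int, cfg: TrainingConfig) -> AutoencoderLayer:
    """Train one sparse auto-encoder layer by full-batch L-BFGS."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("training requires a 2-D sample matrix with at least 2 samples")
    n_in = X.shape[0]
    layer0 = init_layer(n_in, n_hidden, cfg.seed)
    n_eval = [0]

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        n_eval[0] += 1
        layer = _unpack(theta, n_in, n_hidden)
        cost, grads = sparse_cost_and_grad(layer, X, cfg)
        if not np.isfinite(cost):
            raise FloatingPointError(f"non-finite cost at objective evaluation {n_eval[0]}")
        grad_vec = np.concatenate([g.ravel() for g in grads])
        return cost, grad_vec

    theta0 = _pack(layer0)
    cost0, _ = objective(theta0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": cfg.max_iter, "ftol": 1e-10, "gtol": 1e-7},
        )
    if result.fun > cost0:  # descent guarantee; L-BFGS-B should never regress
        return layer0
    return _unpack(result.x, n_in, n_hidden)


def _derived_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] & 0x7FFFFFFF)


def greedy_pretrain(X: np.ndarray, cfg: TrainingConfig) -> list[AutoencoderLayer]:
    """Train the stack layer by layer, each on the previous layer's encodings."""
    X = np.asarray(X, dtype=float)
    sizes = resolve_layer_sizes(cfg, X.shape[0])
    layers: list[AutoencoderLayer] = []
    hidden = X
    for index, n_hidden in enumerate(sizes[1:]):
        layer_cfg = replace(cfg, layer_sizes=None, seed=_derived_seed(cfg.seed, index))
        layer = train_layer(hidden, n_hidden, layer_cfg)
        layers.append(layer)
        hidden = layer.encode(hidden)
    return layers


def stack_encode(layers: Sequence[AutoencoderLayer], X: np.ndarray) -> np.ndarray:
    """Apply the frozen encoder stack; an empty stack is the identity."""
    out = np.asarray(X, dtype=float)
    for layer in layers:
        if out.shape[0] != layer.n_in:
            raise ValueError(
                f"shape mismatch: layer expects {layer.n_in} rows, got {out.shape[0]}"
            )
        out = layer.encode(out)
    return out


def sparsity_stats(layer: AutoencoderLayer, X: np.ndarray) -> SparsityStats:
    rho_hat = layer.encode(np.asarray(X, dtype=float)).mean(axis=1)
    return SparsityStats(rho_hat=rho_hat, n2=layer.n_hidden)


def save_stack(path: str | Path, layers: Sequence[AutoencoderLayer], cfg: TrainingConfig) -> None:
    """Portable JSON checkpoint of the encoder stack and its config."""
    payload = {
        "config": {
            "layer_sizes": list(cfg.layer_sizes) if cfg.layer_sizes is not None else None,
            "delta_wd": cfg.delta_wd,
            "beta": cfg.beta,
            "rho": cfg.rho,
            "max_iter": cfg.max_iter,
            "seed": cfg.seed,
            "regularize_decoder": cfg.regularize_decoder,
        },
        "layers": [
            {
                "W_enc": layer.W_enc.tolist(),
                "b_enc": layer.b_enc.tolist(),
                "W_dec": layer.W_dec.tolist(),
                "b_dec": layer.b_dec.tolist(),
            }
            for layer in layers
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_stack(path: str | Path) -> tuple[list[AutoencoderLayer], TrainingConfig]:
    payload = json.loads(Path(path).read_text())
    cfg = TrainingConfig(**payload["config"])
    layers = [
        AutoencoderLayer(
            W_enc=np.array(entry["W_enc"]),
            b_enc=np.array(entry["b_enc"]),
            W_dec=np.array(entry["W_dec"]),
            b_dec=np.array(entry["b_dec"]),
        )
        for entry in payload["layers"]
    ]
    return layers, cfg
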
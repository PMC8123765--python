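"""Local (first-order) structure features.

A single untrained graph-convolution pass: the symmetrically normalized
self-looped adjacency aggregates neighbor attributes through a randomly
initialized weight matrix and a ReLU, and the raw attributes are re-injected
afterwards so repeated aggregation cannot wash them out.  All supervised
learning happens downstream in the pair classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import NormalizedAdjacency


@dataclass(frozen=True)
class GCNWeights:
    w: np.ndarray  # d_in x d_out
    seed: int


def init_weights(d_in: int, d_out: int, seed: int) -> GCNWeights:
    """Glorot-uniform weights, fully determined by the seed."""
    if d_in < 1 or d_out < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    limit = np.sqrt(6.0 / (d_in + d_out))
    return GCNWeights(w=rng.uniform(-limit, limit, size=(d_in, d_out)), seed=seed)


def gcn_layer(x: np.ndarray, a_norm: NormalizedAdjacency | np.ndarray, w: GCNWeights | np.ndarray) -> np.ndarray:
    """ReLU(A_norm @ X @ W)."""
    a = a_norm.values if isinstance(a_norm, NormalizedAdjacency) else a_norm
    wm = w.w if isinstance(w, GCNWeights) else w
    if a.shape[1] != x.shape[0] or x.shape[1] != wm.shape[0]:
        raise ValueError(
            f"dimension error: a_norm {a.shape}, x {x.shape}, w {wm.shape}"
        )
    return np.maximum(a @ x @ wm, 0.0)


def gf_features(
    x: np.ndarray,
    a_norm: NormalizedAdjacency | np.ndarray,
    w: GCNWeights | np.ndarray,
    n_layers: int = 1,
    mode: str = "concat",
) -> np.ndarray:
    """Stack of aggregation layers with raw-attribute re-injection after each.

    mode "concat" appends the original X to each layer's activation (width
    grows by d_attr per layer); mode "sum" adds X elementwise and requires
    the hidden width to equal d_attr.  Defaults (one layer, concat, 64-dim
    attributes and hidden) give a 128-wide output.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if mode not in ("concat", "sum"):
        raise ValueError(f"unknown combine mode: {mode!r}")
    wm = w.w if isinstance(w, GCNWeights) else w
    seed = w.seed if isinstance(w, GCNWeights) else 0
    d_attr = x.shape[1]
    if mode == "sum" and wm.shape[1] != d_attr:
        raise ValueError("incompatible sum mode: hidden dim must equal d_attr")

    h = x
    for layer in range(n_layers):
        if h.shape[1] != wm.shape[0]:
            # deeper layers see a wider input after concat; re-derive weights
            wm = init_weights(h.shape[1], wm.shape[1], seed + layer).w
        act = gcn_layer(h, a_norm, wm)
        h = np.hstack([act, x]) if mode == "concat" else act + x
    return h
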
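"""Global (high-order) structure features via truncated random walks + skip-gram.

Walk sampling treats the bipartite graph WITHOUT self-loops (in-place loops
would corrupt context statistics).  The skip-gram model is trained by SGD
on (center, context) pairs from sliding windows over the walks; the default
objective is hierarchical softmax over a Huffman tree built from corpus node
frequencies, with negative sampling available as an alternative.  Training
is single-threaded and fully determined by the seed.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import BipartiteGraph

logger = logging.getLogger(__name__)

_MAX_EXP = 8.0  # clamp for sigmoid stability


@dataclass(frozen=True)
class WalkConfig:
    """Hyperparameters for walk sampling and skip-gram training."""

    walk_length: int = 30
    window: int = 5
    epochs: int = 10
    dim: int = 64
    alpha: float = 0.025
    seed: int = 0
    objective: str = "hs"  # "hs" (hierarchical softmax) or "ns" (negative sampling)
    negative: int = 5

    def __post_init__(self) -> None:
        if min(self.walk_length, self.window, self.epochs, self.dim) < 1:
            raise ValueError("walk_length, window, epochs and dim must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.window >= self.walk_length:
            raise ValueError("window must be smaller than walk_length")
        if self.objective not in ("hs", "ns"):
            raise ValueError(f"unknown objective: {self.objective!r}")


@dataclass(frozen=True)
class WalkCorpus:
    walks: list[np.ndarray]
    n_nodes: int


@dataclass(frozen=True)
class EmbeddingMatrix:
    psi: np.ndarray  # |V| x dim


def random_walk(
    adjacency_lists: list[np.ndarray],
    start: int,
    t: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform random walk of (up to) t nodes starting at ``start``.

    Halts early at a node with no neighbors; callers discard walks shorter
    than 2 nodes.
    """
    if not 0 <= start < len(adjacency_lists):
        raise ValueError(f"invalid start index: {start}")
    if t < 1:
        raise ValueError("walk length must be >= 1")
    walk = np.empty(t, dtype=np.int64)
    walk[0] = start
    cur = start
    for step in range(1, t):
        nbrs = adjacency_lists[cur]
        if len(nbrs) == 0:
            return walk[:step]
        cur = nbrs[rng.integers(len(nbrs))]
        walk[step] = cur
    return walk


def build_corpus(g: BipartiteGraph, cfg: WalkConfig) -> WalkCorpus:
    """Walk corpus: per epoch, nodes are shuffled and one walk starts at each."""
    if g.n_edges == 0:
        raise ValueError("no walkable edges")
    adj = g.adjacency_lists()
    rng = np.random.default_rng(cfg.seed)
    walks: list[np.ndarray] = []
    n_discarded = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(g.n_nodes)
        for start in order:
            walk = random_walk(adj, int(start), cfg.walk_length, rng)
            if len(walk) >= 2:
                walks.append(walk)
            else:
                n_discarded += 1
    if n_discarded:
        logger.warning("discarded %d length-1 walks from isolated nodes", n_discarded)
    return WalkCorpus(walks=walks, n_nodes=g.n_nodes)


def context_pairs(walk: np.ndarray | list[int], w: int) -> list[tuple[int, int]]:
    """(center, context) pairs within a window of w positions on either side."""
    if w < 1:
        raise ValueError("window must be >= 1")
    seq = list(walk)
    pairs = []
    for j, center in enumerate(seq):
        lo, hi = max(0, j - w), min(len(seq), j + w + 1)
        for k in range(lo, hi):
            if k != j:
                pairs.append((center, seq[k]))
    return pairs


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_MAX_EXP, _MAX_EXP)))


def _huffman_paths(freqs: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Huffman coding of nodes by corpus frequency.

    Returns per-node arrays of inner-node indices (points) and binary codes
    along the root-to-leaf path.  Nodes with zero frequency get empty paths.
    """
    active = np.flatnonzero(freqs)
    if len(active) == 0:
        raise ValueError("nothing to train on")
    n = len(freqs)
    points: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(n)]
    codes: list[np.ndarray] = [np.empty(0, dtype=np.float64) for _ in range(n)]
    if len(active) == 1:
        return points, codes

    # heap entries: (freq, tiebreak, node_key); leaves keyed 0..n-1,
    # inner nodes keyed n, n+1, ...
    heap: list[tuple[float, int, int]] = [
        (float(freqs[i]), int(i), int(i)) for i in active
    ]
    heapq.heapify(heap)
    parent: dict[int, tuple[int, int]] = {}  # child key -> (inner index, code bit)
    next_key = n
    n_inner = 0
    while len(heap) > 1:
        f1, _, k1 = heapq.heappop(heap)
        f2, _, k2 = heapq.heappop(heap)
        inner = n_inner
        n_inner += 1
        parent[k1] = (inner, 0)
        parent[k2] = (inner, 1)
        heapq.heappush(heap, (f1 + f2, next_key, next_key))
        next_key += 1

    for leaf in active:
        pts: list[int] = []
        cds: list[int] = []
        key = int(leaf)
        while key in parent:
            inner, bit = parent[key]
            pts.append(inner)
            cds.append(bit)
            key = inner + n  # inner node's heap key
        # collected leaf-to-root; reverse to root-to-leaf
        points[leaf] = np.asarray(pts[::-1], dtype=np.int64)
        codes[leaf] = np.asarray(cds[::-1], dtype=np.float64)
    return points, codes


class SkipGramTrainer:
    """SGD skip-gram over walk corpora; exposes per-pass training and the
    total negative log-likelihood so descent can be verified directly."""

    def __init__(self, corpus: WalkCorpus, cfg: WalkConfig):
        if not corpus.walks:
            raise ValueError("nothing to train on")
        self.cfg = cfg
        self.n_nodes = corpus.n_nodes
        self.rng = np.random.default_rng(cfg.seed + 1)
        freqs = np.zeros(self.n_nodes, dtype=np.float64)
        for walk in corpus.walks:
            np.add.at(freqs, walk, 1.0)
        self.freqs = freqs
        self.psi = (self.rng.random((self.n_nodes, cfg.dim)) - 0.5) / cfg.dim
        self.psi[freqs == 0] = 0.0
        if cfg.objective == "hs":
            self.points, self.codes = _huffman_paths(freqs)
            n_inner = max(int(np.count_nonzero(freqs)) - 1, 1)
            self.syn1 = np.zeros((n_inner, cfg.dim))
        else:
            self.syn1 = np.zeros((self.n_nodes, cfg.dim))
            noise = freqs**0.75
            self.noise_p = noise / noise.sum()

    def _update_hs(self, center: int, context: int, lr: float) -> None:
        pts = self.points[context]
        if len(pts) == 0:
            return
        h = self.psi[center]
        out = self.syn1[pts]
        f = _sigmoid(out @ h)
        g = (1.0 - self.codes[context] - f) * lr
        neu1e = g @ out
        self.syn1[pts] += np.outer(g, h)
        self.psi[center] += neu1e

    def _update_ns(self, center: int, context: int, lr: float) -> None:
        targets = np.empty(self.cfg.negative + 1, dtype=np.int64)
        targets[0] = context
        targets[1:] = self.rng.choice(
            self.n_nodes, size=self.cfg.negative, p=self.noise_p
        )
        labels = np.zeros(len(targets))
        labels[0] = 1.0
        h = self.psi[center]
        out = self.syn1[targets]
        f = _sigmoid(out @ h)
        g = (labels - f) * lr
        neu1e = g @ out
        np.add.at(self.syn1, targets, np.outer(g, h))
        self.psi[center] += neu1e

    def train_pass(self, corpus: WalkCorpus, lr_start: float, lr_end: float | None = None) -> None:
        """One pass over the corpus; lr decays linearly from lr_start to lr_end."""
        if lr_end is None:
            lr_end = lr_start
        update = self._update_hs if self.cfg.objective == "hs" else self._update_ns
        w = self.cfg.window
        total = sum(
            min(j + w + 1, len(walk)) - max(0, j - w) - 1
            for walk in corpus.walks
            for j in range(len(walk))
        )
        done = 0
        for walk in corpus.walks:
            seq = walk.tolist()
            length = len(seq)
            for j, center in enumerate(seq):
                lo, hi = max(0, j - w), min(length, j + w + 1)
                for k in range(lo, hi):
                    if k == j:
                        continue
                    lr = lr_start + (lr_end - lr_start) * (done / max(total, 1))
                    update(center, seq[k], lr)
                    done += 1

    def objective(self, corpus: WalkCorpus) -> float:
        """Total -log Pr(context | center) under the current parameters."""
        total = 0.0
        w = self.cfg.window
        for walk in corpus.walks:
            for center, context in context_pairs(walk, w):
                if self.cfg.objective == "hs":
                    pts = self.points[context]
                    if len(pts) == 0:
                        continue
                    z = self.syn1[pts] @ self.psi[center]
                    signs = 1.0 - 2.0 * self.codes[context]
                    total -= np.log(_sigmoid(signs * z)).sum()
                else:
                    z = self.syn1[context] @ self.psi[center]
                    total -= float(np.log(_sigmoid(z)))
        return float(total)

    def embedding(self) -> EmbeddingMatrix:
        return EmbeddingMatrix(psi=self.psi.copy())


def train_skipgram(corpus: WalkCorpus, cfg: WalkConfig) -> EmbeddingMatrix:
    """Train skip-gram over the corpus; lr decays linearly to alpha/100."""
    trainer = SkipGramTrainer(corpus, cfg)
    trainer.train_pass(corpus, cfg.alpha, cfg.alpha / 100.0)
    return trainer.embedding()


def embed_nodes(g: BipartiteGraph, cfg: WalkConfig) -> EmbeddingMatrix:
    """End-to-end node embedding: walk corpus then skip-gram training.

    Isolated nodes start no usable walks and receive zero-vector rows.
    """
    corpus = build_corpus(g, cfg)
    emb = train_skipgram(corpus, cfg)
    isolated = np.flatnonzero(g.degrees() == 0)
    if len(isolated):
        logger.warning("%d isolated nodes got zero embeddings", len(isolated))
        emb.psi[isolated] = 0.0
    return emb


def dump_corpus(corpus: WalkCorpus, path: str) -> None:
    """One walk per line, space-separated node indices (word2vec-compatible)."""
    with open(path, "w") as fh:
        for walk in corpus.walks:
            fh.write(" ".join(str(int(v)) for v in walk) + "\n")
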
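"""Structural node embeddings via biased random walks + skip-gram.

Walks treat the graph as undirected and untyped (relation semantics
enter only in the GNN).  Second-order transition weights follow the
usual return/in-out parameterization: unnormalized weight ``1/p`` to
step back to the previous node, ``1`` to a common neighbor of previous
and current, ``1/q`` otherwise.  With ``p == q == 1`` this reduces to a
first-order uniform walk, which we vectorize.

Skip-gram with negative sampling is implemented directly on numpy (no
external word-embedding dependency); minibatched SGD with a linearly
decaying learning rate, seeded and deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class WalkConfig:
    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 5
    dim: int = 32
    epochs: int = 5
    negatives: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ConfigurationError("p and q must be positive")
        if self.dim < 2:
            raise ConfigurationError("embedding dimension must be >= 2")
        if self.walk_length < 2:
            raise ConfigurationError("walk_length must be >= 2")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _adjacency(graph) -> tuple[np.ndarray, np.ndarray, list]:
    """Return (indptr, indices, node order) for a KnowledgeGraph or nx.Graph."""
    if hasattr(graph, "undirected_adjacency"):
        indptr, indices = graph.undirected_adjacency()
        return indptr, indices, list(graph.node_ids)
    # assume networkx-like
    nodes = list(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    pairs = set()
    for a, b in graph.edges():
        ia, ib = index[a], index[b]
        if ia != ib:
            pairs.add((ia, ib))
            pairs.add((ib, ia))
    n = len(nodes)
    if pairs:
        arr = np.array(sorted(pairs), dtype=np.intp)
        counts = np.bincount(arr[:, 0], minlength=n)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        indices = arr[:, 1]
    else:
        indptr = np.zeros(n + 1, dtype=np.intp)
        indices = np.array([], dtype=np.intp)
    return indptr, indices, nodes


def generate_walks(graph, cfg: WalkConfig) -> tuple[list[np.ndarray], int]:
    """Seeded walk corpus: ``walks_per_node`` walks from every node.

    Isolated nodes yield length-1 walks.  Returns (walks as index
    arrays, number of nodes).
    """
    indptr, indices, nodes = _adjacency(graph)
    n = len(nodes)
    rng = np.random.default_rng(cfg.seed)
    deg = np.diff(indptr)

    if cfg.p == 1.0 and cfg.q == 1.0:
        walks = _first_order_walks(indptr, indices, deg, n, cfg, rng)
    else:
        walks = _second_order_walks(indptr, indices, deg, n, cfg, rng)
    return walks, n


def _first_order_walks(indptr, indices, deg, n, cfg, rng):
    starts = np.repeat(np.arange(n), cfg.walks_per_node)
    m = len(starts)
    steps = np.empty((m, cfg.walk_length), dtype=np.intp)
    steps[:, 0] = starts
    movable = deg[starts] > 0
    for t in range(1, cfg.walk_length):
        cur = steps[:, t - 1]
        draw = rng.random(m)
        nxt = cur.copy()
        mv = movable
        offs = (draw[mv] * deg[cur[mv]]).astype(np.intp)
        nxt[mv] = indices[indptr[cur[mv]] + offs]
        steps[:, t] = nxt
    walks = []
    for i in range(m):
        walks.append(steps[i] if movable[i] else steps[i, :1])
    return walks


def _second_order_walks(indptr, indices, deg, n, cfg, rng):
    nbrs = [indices[indptr[v]:indptr[v + 1]] for v in range(n)]
    nbr_sets = [set(a.tolist()) for a in nbrs]
    walks = []
    for start in range(n):
        for _ in range(cfg.walks_per_node):
            if deg[start] == 0:
                walks.append(np.array([start], dtype=np.intp))
                continue
            walk = [start]
            cur = int(rng.choice(nbrs[start]))
            walk.append(cur)
            while len(walk) < cfg.walk_length:
                prev = walk[-2]
                cand = nbrs[cur]
                w = np.where(cand == prev, 1.0 / cfg.p,
                             np.where([c in nbr_sets[prev] for c in cand],
                                      1.0, 1.0 / cfg.q))
                nxt = int(rng.choice(cand, p=w / w.sum()))
                walk.append(nxt)
                cur = nxt
            walks.append(np.array(walk, dtype=np.intp))
    return walks


def _window_pairs(walks: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for w in walks:
        L = len(w)
        for off in range(1, window + 1):
            if L <= off:
                continue
            a, b = w[:-off], w[off:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    if not centers:
        return np.array([], dtype=np.intp), np.array([], dtype=np.intp)
    return np.concatenate(centers), np.concatenate(contexts)


def train_skipgram(walks: list[np.ndarray], n_nodes: int, cfg: WalkConfig,
                   batch_size: int | None = None) -> np.ndarray:
    """Skip-gram with negative sampling over windowed walk co-occurrences.

    Deterministic given ``cfg.seed``.  Nodes absent from every window
    keep their seeded random initialization.  The minibatch size scales
    with the node count so that no node accumulates a huge summed update
    within one batch (which destabilizes training on small graphs).
    """
    if cfg.dim < 1:
        raise ConfigurationError("embedding dimension must be >= 1")
    if batch_size is None:
        batch_size = int(np.clip(4 * n_nodes, 64, 4096))
    rng = np.random.default_rng(cfg.seed + 1)
    dim = cfg.dim
    w_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    w_out = np.zeros((n_nodes, dim))

    centers, contexts = _window_pairs(walks, cfg.window)
    n_pairs = len(centers)
    if n_pairs == 0:
        return w_in

    tok_counts = np.zeros(n_nodes)
    for w in walks:
        np.add.at(tok_counts, w, 1.0)
    noise = tok_counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    lr0, lr_min = 0.025, 1e-4
    n_batches = cfg.epochs * int(np.ceil(n_pairs / batch_size))
    b = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            idx = order[lo:lo + batch_size]
            c, o = centers[idx], contexts[idx]
            lr = max(lr0 * (1.0 - b / n_batches), lr_min)
            b += 1
            neg = np.searchsorted(noise_cdf, rng.random((len(idx), cfg.negatives)))
            vc = w_in[c]
            vo = w_out[o]
            g_pos = (1.0 - expit(np.sum(vc * vo, axis=1))) * lr
            d_vc = g_pos[:, None] * vo
            np.add.at(w_out, o, g_pos[:, None] * vc)
            vn = w_out[neg]                                   # B x K x d
            g_neg = -expit(np.einsum("bd,bkd->bk", vc, vn)) * lr
            d_vc += np.einsum("bk,bkd->bd", g_neg, vn)
            np.add.at(w_out, neg.ravel(),
                      (g_neg[:, :, None] * vc[:, None, :]).reshape(-1, dim))
            np.add.at(w_in, c, d_vc)
    return w_in


@dataclass
class EmbeddingMatrix:
    """One structural embedding row per graph node."""

    node_ids: list[str]
    vectors: np.ndarray

    def __post_init__(self):
        if len(self.node_ids) != self.vectors.shape[0]:
            raise ValueError("one row per node required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node_id: str) -> np.ndarray:
        return self.vectors[self.node_ids.index(node_id)]

    def to_tsv(self, path, config_hash: str = "") -> None:
        with open(path, "w") as fh:
            fh.write(f"#dim={self.dim}\tconfig_hash={config_hash}\n")
            for nid, vec in zip(self.node_ids, self.vectors):
                fh.write(nid + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "EmbeddingMatrix":
        ids, rows = [], []
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("missing embedding header line")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(node_ids=ids, vectors=np.array(rows))


def node2vec_embeddings(graph, cfg: WalkConfig) -> EmbeddingMatrix:
    """End-to-end structural view: walks then skip-gram, one call."""
    walks, n = generate_walks(graph, cfg)
    vectors = train_skipgram(walks, n, cfg)
    ids = list(graph.node_ids) if hasattr(graph, "node_ids") else list(graph.nodes())
    return EmbeddingMatrix(node_ids=[str(i) for i in ids], vectors=vectors)
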
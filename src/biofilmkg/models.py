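"""Graph neural models: relation-aware attention network plus GAT/GCN baselines.

The relation-aware model ("relgat") shares one attention mechanism
across all edge types but concatenates a learned per-relation embedding
into every attention logit, so edge semantics modulate attention without
per-relation weight matrices.  The GAT baseline is the identical
architecture with the relation block removed (all edges treated
uniformly); the GCN baseline uses the symmetric normalized adjacency.

Architecture: feature projection to a 32-dimensional hidden space, two
graph layers (32 -> 32), and a softmax classification head, with dropout
0.3 on layer inputs and batch normalization after aggregation.
Self-loops carry a learned scalar weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import GatedFusion
from .nn import (BatchNorm1d, Tensor, dropout, log_softmax, scatter_sum,
                 segment_softmax)

MODEL_KINDS = ("relgat", "gat", "gcn")


class VocabularyError(ValueError):
    pass


@dataclass
class GraphTensors:
    """Index arrays for message passing plus the normalized adjacency."""

    n_nodes: int
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_rel: np.ndarray
    n_relations: int
    a_hat: np.ndarray | None = None


def graph_tensors(graph, with_adjacency: bool = True) -> GraphTensors:
    """Build message-passing arrays from a KnowledgeGraph.

    Directed relations (INFECTS, ENRICHED_AT, IS_A) are mirrored with
    reverse edges carrying the same relation id; CO_OCCURS is already
    stored in both directions.
    """
    index = graph.node_index
    rel_index = {r: i for i, r in enumerate(graph.relations)}
    src, dst, rel = [], [], []
    for s, r, d in graph.edges:
        si, di, ri = index[s], index[d], rel_index[r]
        src.append(si)
        dst.append(di)
        rel.append(ri)
        if r != "CO_OCCURS":
            src.append(di)
            dst.append(si)
            rel.append(ri)
    src = np.asarray(src, dtype=np.intp)
    dst = np.asarray(dst, dtype=np.intp)
    rel = np.asarray(rel, dtype=np.intp)
    a_hat = None
    if with_adjacency:
        A = np.zeros((graph.n_nodes, graph.n_nodes))
        A[src, dst] = 1.0
        A[dst, src] = 1.0
        a_hat = normalize_adjacency(A)
    return GraphTensors(n_nodes=graph.n_nodes, edge_src=src, edge_dst=dst,
                        edge_rel=rel, n_relations=len(graph.relations),
                        a_hat=a_hat)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^(-1/2) (A + I) D^(-1/2)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    At = A + np.eye(A.shape[0])
    d = At.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return dinv[:, None] * At * dinv[None, :]


@dataclass
class ModelOutput:
    """Per-node class probabilities plus the final hidden representations."""

    probs: Tensor       # N x 2, rows sum to 1
    log_probs: Tensor   # N x 2
    hidden: Tensor      # N x hidden, input to the classification head


def _glorot(rng, shape):
    lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-lim, lim, shape)


class RelationAttentionLayer:
    """One attention layer; relation-aware iff a relation table is given.

    For an edge j -> i with relation k the logit is
    ``leaky_relu(a^T [W h_i || W h_j || r_k])``; attention is softmax over
    the in-neighborhood of i including a self-loop whose message is
    scaled by a learned scalar.  Output is BatchNorm(ReLU(aggregate)).
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 relation_emb: Tensor | None = None, dropout_rate: float = 0.3,
                 negative_slope: float = 0.2):
        r_dim = 0 if relation_emb is None else relation_emb.shape[1]
        self.W = Tensor(_glorot(rng, (d_in, d_out)), requires_grad=True)
        # small attention vector => near-uniform attention at init (behaves
        # like mean aggregation early, which stabilizes the first epochs)
        self.a = Tensor(rng.normal(0.0, 0.01, (2 * d_out + r_dim, 1)), requires_grad=True)
        self.s = Tensor(np.ones((1, 1)), requires_grad=True)
        self.bn = BatchNorm1d(d_out)
        self.relation_emb = relation_emb
        self.dropout_rate = dropout_rate
        self.negative_slope = negative_slope

    def __call__(self, x: Tensor, gt: GraphTensors, training: bool = False,
                 rng: np.random.Generator | None = None,
                 relation_ids: np.ndarray | None = None,
                 include_self: bool = True) -> Tensor:
        n = gt.n_nodes
        rel = gt.edge_rel if relation_ids is None else np.asarray(relation_ids)
        if self.relation_emb is not None and len(rel) and rel.max() >= self.relation_emb.shape[0] - 1:
            raise VocabularyError(
                f"relation id {int(rel.max())} outside vocabulary of size "
                f"{self.relation_emb.shape[0] - 1}")

        x = dropout(x, self.dropout_rate, rng, training)
        h = x @ self.W
        if include_self:
            loop = np.arange(n)
            all_src = np.concatenate([gt.edge_src, loop])
            all_dst = np.concatenate([gt.edge_dst, loop])
        else:
            all_src, all_dst = gt.edge_src, gt.edge_dst
        hi = h.gather(all_dst)
        hj = h.gather(all_src)
        if self.relation_emb is not None:
            self_rel = self.relation_emb.shape[0] - 1
            all_rel = np.concatenate([rel, np.full(n, self_rel)]) if include_self else rel
            rk = self.relation_emb.gather(all_rel)
            feat = Tensor.cat([hi, hj, rk], axis=1)
        else:
            feat = Tensor.cat([hi, hj], axis=1)
        logits = (feat @ self.a).reshape(-1).leaky_relu(self.negative_slope)
        alpha = segment_softmax(logits, all_dst, n)
        e = len(gt.edge_src)
        if include_self:
            scale = Tensor.cat([Tensor(np.ones((e, 1))),
                                self.s * Tensor(np.ones((n, 1)))], axis=0)
            msg = hj * scale
        else:
            msg = hj
        out = scatter_sum(msg * alpha.reshape(-1, 1), all_dst, n)
        return self.bn(out.relu(), training)

    def attention(self, x: Tensor, gt: GraphTensors) -> np.ndarray:
        """Eval-mode attention coefficients (edges then self-loops)."""
        h = x @ self.W
        n = gt.n_nodes
        loop = np.arange(n)
        all_src = np.concatenate([gt.edge_src, loop])
        all_dst = np.concatenate([gt.edge_dst, loop])
        hi, hj = h.gather(all_dst), h.gather(all_src)
        if self.relation_emb is not None:
            all_rel = np.concatenate([gt.edge_rel,
                                      np.full(n, self.relation_emb.shape[0] - 1)])
            feat = Tensor.cat([hi, hj, self.relation_emb.gather(all_rel)], axis=1)
        else:
            feat = Tensor.cat([hi, hj], axis=1)
        logits = (feat @ self.a).reshape(-1).leaky_relu(self.negative_slope)
        return segment_softmax(logits, all_dst, n).data

    def parameters(self):
        return [self.W, self.a, self.s] + self.bn.parameters()

    def named_parameters(self, prefix=""):
        return [(f"{prefix}.W", self.W), (f"{prefix}.a", self.a),
                (f"{prefix}.s", self.s), (f"{prefix}.bn.gamma", self.bn.gamma),
                (f"{prefix}.bn.beta", self.bn.beta)]


class AttentionBackbone:
    """Projection -> two attention layers -> softmax head."""

    def __init__(self, d_in: int, hidden: int, n_classes: int,
                 rng: np.random.Generator, n_relations: int | None,
                 r_dim: int = 8, dropout_rate: float = 0.3):
        self.relational = n_relations is not None
        self.relation_emb = None
        if self.relational:
            # one row per relation plus a trailing self-loop row, shared by both layers
            self.relation_emb = Tensor(rng.normal(0.0, 0.1, (n_relations + 1, r_dim)),
                                       requires_grad=True)
        self.W_in = Tensor(_glorot(rng, (d_in, hidden)), requires_grad=True)
        self.b_in = Tensor(np.zeros(hidden), requires_grad=True)
        self.layer1 = RelationAttentionLayer(hidden, hidden, rng, self.relation_emb,
                                             dropout_rate)
        self.layer2 = RelationAttentionLayer(hidden, hidden, rng, self.relation_emb,
                                             dropout_rate)
        self.W_out = Tensor(_glorot(rng, (hidden, n_classes)), requires_grad=True)
        self.b_out = Tensor(np.zeros(n_classes), requires_grad=True)

    def forward(self, x: Tensor, gt: GraphTensors, training: bool = False,
                rng=None, relation_ids=None) -> ModelOutput:
        h = (x @ self.W_in + self.b_in).relu()
        h = self.layer1(h, gt, training, rng, relation_ids)
        h = self.layer2(h, gt, training, rng, relation_ids)
        logits = h @ self.W_out + self.b_out
        lp = log_softmax(logits)
        return ModelOutput(probs=lp.exp(), log_probs=lp, hidden=h)

    def parameters(self):
        params = [self.W_in, self.b_in]
        if self.relation_emb is not None:
            params.append(self.relation_emb)
        params += self.layer1.parameters() + self.layer2.parameters()
        params += [self.W_out, self.b_out]
        return params

    def named_parameters(self):
        out = [("proj.W", self.W_in), ("proj.b", self.b_in)]
        if self.relation_emb is not None:
            out.append(("relations.emb", self.relation_emb))
        out += self.layer1.named_parameters("layer1")
        out += self.layer2.named_parameters("layer2")
        out += [("head.W", self.W_out), ("head.b", self.b_out)]
        return out

    def batchnorms(self):
        return [self.layer1.bn, self.layer2.bn]


class GCNBackbone:
    """Two layers of A_hat X W with ReLU + dropout between, softmax head."""

    def __init__(self, d_in: int, hidden: int, n_classes: int,
                 rng: np.random.Generator, dropout_rate: float = 0.3):
        self.W1 = Tensor(_glorot(rng, (d_in, hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W2 = Tensor(_glorot(rng, (hidden, hidden)), requires_grad=True)
        self.b2 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W_out = Tensor(_glorot(rng, (hidden, n_classes)), requires_grad=True)
        self.b_out = Tensor(np.zeros(n_classes), requires_grad=True)
        self.dropout_rate = dropout_rate

    def forward(self, x: Tensor, gt: GraphTensors, training: bool = False,
                rng=None, relation_ids=None) -> ModelOutput:
        if gt.a_hat is None:
            raise RuntimeError("GCN requires a precomputed normalized adjacency")
        A = Tensor(gt.a_hat)
        h = (A @ (x @ self.W1 + self.b1)).relu()
        h = dropout(h, self.dropout_rate, rng, training)
        h = (A @ (h @ self.W2 + self.b2)).relu()
        logits = h @ self.W_out + self.b_out
        lp = log_softmax(logits)
        return ModelOutput(probs=lp.exp(), log_probs=lp, hidden=h)

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W_out, self.b_out]

    def named_parameters(self):
        return [("gcn1.W", self.W1), ("gcn1.b", self.b1),
                ("gcn2.W", self.W2), ("gcn2.b", self.b2),
                ("head.W", self.W_out), ("head.b", self.b_out)]

    def batchnorms(self):
        return []


class HostDiseaseModel:
    """Gated fusion of (raw features, structural embedding) + a graph backbone.

    ``kind`` selects the backbone: "relgat" (relation-aware attention),
    "gat" (relation-blind attention) or "gcn".
    """

    def __init__(self, kind: str, n_raw_features: int, embed_dim: int,
                 n_relations: int, hidden: int = 32, n_classes: int = 2,
                 r_dim: int = 8, dropout_rate: float = 0.3, seed: int = 0):
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
        self.kind = kind
        rng = np.random.default_rng(seed)
        self.fusion = GatedFusion(n_raw_features, embed_dim, rng)
        if kind == "relgat":
            self.backbone = AttentionBackbone(embed_dim, hidden, n_classes, rng,
                                              n_relations, r_dim, dropout_rate)
        elif kind == "gat":
            self.backbone = AttentionBackbone(embed_dim, hidden, n_classes, rng,
                                              None, 0, dropout_rate)
        else:
            self.backbone = GCNBackbone(embed_dim, hidden, n_classes, rng,
                                        dropout_rate)

    def forward(self, x_raw: np.ndarray, z: np.ndarray, gt: GraphTensors,
                training: bool = False, rng=None,
                relation_ids=None) -> ModelOutput:
        f, _, _ = self.fusion(Tensor(x_raw), Tensor(z))
        return self.backbone.forward(f, gt, training, rng, relation_ids)

    def parameters(self):
        return self.fusion.parameters() + self.backbone.parameters()

    def named_parameters(self):
        return self.fusion.named_parameters() + self.backbone.named_parameters()

    # -- state snapshot (parameters + batch-norm buffers) --------------
    def get_state(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for bn in self.backbone.batchnorms():
            state += [b.copy() for b in bn.buffers()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, d in zip(params, state[:len(params)]):
            p.data = d.copy()
        rest = state[len(params):]
        for bn in self.backbone.batchnorms():
            bn.set_buffers(rest[:2])
            rest = rest[2:]


def count_parameters(model) -> tuple[int, dict[str, int]]:
    """Total trainable scalar count with a per-block breakdown.

    Accepts anything with ``named_parameters()`` or ``parameters()``, or
    a plain iterable of tensors.
    """
    if hasattr(model, "named_parameters"):
        named = model.named_parameters()
    elif hasattr(model, "parameters"):
        named = [(f"param{i}", p) for i, p in enumerate(model.parameters())]
    else:
        named = [(f"param{i}", p) for i, p in enumerate(model)]
    breakdown = {name: int(np.asarray(p.data).size) for name, p in named}
    return sum(breakdown.values()), breakdown
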
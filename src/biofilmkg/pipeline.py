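"""End-to-end experiment wiring shared by the CLI and the test suite.

Stages: synthetic data -> link holdout -> co-occurrence screen -> graph
build + labels -> structural embeddings -> split/standardize -> train ->
evaluate (classification, link prediction, site scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kg, metrics, synth
from .models import GraphTensors, HostDiseaseModel, count_parameters, graph_tensors
from .node2vec import EmbeddingMatrix, WalkConfig, node2vec_embeddings
from .train import SplitMasks, TrainConfig, stratified_split, train_model, zscore_features


@dataclass
class ExperimentBundle:
    """Everything upstream of model fitting, computed once per config."""

    table: kg.MicrobeTable
    truth: synth.GroundTruth
    graph: kg.KnowledgeGraph
    train_pairs: set
    test_pairs: set
    embeddings: EmbeddingMatrix
    gt: GraphTensors
    labels: np.ndarray = field(default=None)  # int per node; -1 = unlabeled

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.labels >= 0


def build_bundle(synth_cfg: synth.SynthConfig | None = None,
                 walk_cfg: WalkConfig | None = None,
                 holdout_fraction: float = 0.2,
                 with_adjacency: bool = True) -> ExperimentBundle:
    synth_cfg = synth_cfg or synth.SynthConfig()
    walk_cfg = walk_cfg or WalkConfig()
    table, truth = synth.generate_dataset(synth_cfg)
    train_pairs, test_pairs = synth.hold_out_infects(truth, holdout_fraction,
                                                     synth_cfg.seed)
    cooc = kg.spearman_cooccurrence(table.sample_matrix, taxa=table.taxon_ids)
    graph = kg.build_graph(table, cooc, exclude_infects=test_pairs)
    kg.assign_disease_labels(graph)
    emb = node2vec_embeddings(graph, walk_cfg)
    gt = graph_tensors(graph, with_adjacency=with_adjacency)
    labels = label_array(graph)
    return ExperimentBundle(table=table, truth=truth, graph=graph,
                            train_pairs=train_pairs, test_pairs=test_pairs,
                            embeddings=emb, gt=gt, labels=labels)


def label_array(graph: kg.KnowledgeGraph,
                supervised_types=("Virus", "Phage")) -> np.ndarray:
    """Per-node integer labels (1 = disease, 0 = health, -1 = unsupervised)."""
    y = np.full(graph.n_nodes, -1, dtype=int)
    for i, (nid, ntype) in enumerate(zip(graph.node_ids, graph.node_types)):
        if ntype in supervised_types and nid in graph.labels:
            y[i] = 1 if graph.labels[nid] == kg.DISEASE else 0
    return y


def expand_masks(sub_masks: SplitMasks, labeled_idx: np.ndarray,
                 n_nodes: int) -> SplitMasks:
    def expand(m):
        full = np.zeros(n_nodes, dtype=bool)
        full[labeled_idx[m]] = True
        return full

    return SplitMasks(train=expand(sub_masks.train), val=expand(sub_masks.val),
                      test=expand(sub_masks.test))


def split_nodes(bundle: ExperimentBundle, split_seed: int = 42) -> SplitMasks:
    labeled_idx = np.where(bundle.labeled_mask)[0]
    sub = stratified_split(bundle.labels[labeled_idx], seed=split_seed)
    return expand_masks(sub, labeled_idx, bundle.graph.n_nodes)


def fit_model(bundle: ExperimentBundle, kind: str, train_cfg: TrainConfig,
              masks: SplitMasks | None = None, split_seed: int = 42):
    """Train one model on the bundle; returns (model, history, masks, x_std)."""
    if masks is None:
        masks = split_nodes(bundle, split_seed)
    graph = bundle.graph
    x_std = zscore_features(graph.features, graph.n_numeric_features, masks.train)
    model = HostDiseaseModel(
        kind, n_raw_features=x_std.shape[1], embed_dim=bundle.embeddings.dim,
        n_relations=len(graph.relations), hidden=train_cfg.hidden,
        dropout_rate=train_cfg.dropout, seed=train_cfg.seed)
    model, history = train_model(model, x_std, bundle.embeddings.vectors,
                                 bundle.gt, bundle.labels, masks, train_cfg)
    return model, history, masks, x_std


def evaluate_model(bundle: ExperimentBundle, model: HostDiseaseModel,
                   masks: SplitMasks, x_std: np.ndarray, history: dict,
                   hits_k: int = 10, eval_seed: int = 0,
                   relation_ids: np.ndarray | None = None) -> dict:
    """Full metric bundle for one trained model."""
    out = model.forward(x_std, bundle.embeddings.vectors, bundle.gt,
                        training=False, relation_ids=relation_ids)
    probs = out.probs.data
    hidden = out.hidden.data
    y = bundle.labels
    test = masks.test
    preds = probs.argmax(axis=1)
    counts = metrics.confusion_from_predictions(y[test], preds[test])
    cls = metrics.confusion_metrics(counts)
    cls.auc_roc = metrics.roc_auc(probs[test, 1], y[test])

    result = {
        "classification": cls.as_dict(),
        "confusion": {"tp": counts.tp, "fn": counts.fn,
                      "tn": counts.tn, "fp": counts.fp},
        "site_scores": metrics.site_disease_scores(probs[:, 1], bundle.graph),
        "history": {"best_epoch": history["best_epoch"],
                    "stopped_epoch": history["stopped_epoch"],
                    "best_val_loss": history["best_val_loss"]},
        "n_parameters": count_parameters(model)[0],
    }
    if bundle.test_pairs:
        lp = metrics.link_prediction_eval(hidden, bundle.graph, bundle.test_pairs,
                                          known_pairs=bundle.truth.infects_pairs,
                                          k=hits_k, seed=eval_seed)
        result["link_prediction"] = lp.as_dict()
    return result


def run_experiment(bundle: ExperimentBundle, kind: str, train_cfg: TrainConfig,
                   hits_k: int = 10, eval_seed: int = 0,
                   split_seed: int = 42) -> dict:
    model, history, masks, x_std = fit_model(bundle, kind, train_cfg,
                                             split_seed=split_seed)
    result = evaluate_model(bundle, model, masks, x_std, history,
                            hits_k=hits_k, eval_seed=eval_seed)
    result["model"] = kind
    result["_objects"] = {"model": model, "masks": masks, "x_std": x_std,
                          "history": history}
    return result


def shuffle_relations(gt: GraphTensors, seed: int = 0) -> np.ndarray:
    """Permuted copy of the relation ids (ablation input)."""
    rng = np.random.default_rng(seed)
    return gt.edge_rel[rng.permutation(len(gt.edge_rel))]
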
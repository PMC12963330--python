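"""Classification, ranking and site-level evaluation metrics.

Per-class precision/recall/F1 are combined by support-weighted
averaging (the convention under which the printed confusion counts of
the reference experiment reproduce its summary table).  ROC-AUC uses
the Mann-Whitney convention (ties get half credit); PR-AUC is the area
under the step-wise precision-recall curve.  Link prediction scores an
edge as sigmoid of the endpoints' hidden-representation inner product
and reports ROC/PR over sampled negatives plus filtered Hits@K / MRR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; the positive class is "disease"."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class ClassificationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    auc_roc: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class LinkPredMetrics:
    roc_auc: float
    pr_auc: float
    hits_at_k: float
    mrr: float
    k: int
    n_positives: int

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()))


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def confusion_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """All threshold-based metrics derivable from the confusion counts."""
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    n = counts.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    pos, neg = tp + fn, tn + fp
    accuracy = (tp + tn) / n
    sensitivity = _safe_div(tp, pos)
    specificity = _safe_div(tn, neg)

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0

    prec_pos = _safe_div(tp, tp + fp)
    prec_neg = _safe_div(tn, tn + fn)
    rec_pos, rec_neg = sensitivity, specificity
    f1_pos = _safe_div(2 * prec_pos * rec_pos, prec_pos + rec_pos)
    f1_neg = _safe_div(2 * prec_neg * rec_neg, prec_neg + rec_neg)

    w_prec = (pos * prec_pos + neg * prec_neg) / n
    w_rec = (pos * rec_pos + neg * rec_neg) / n
    w_f1 = (pos * f1_pos + neg * f1_neg) / n
    return ClassificationMetrics(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        mcc=mcc, weighted_precision=w_prec, weighted_recall=w_rec,
        weighted_f1=w_f1)


def roc_auc(scores, labels) -> float:
    """Exact AUC: P(score_pos > score_neg) + half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks give tie handling exactly
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Area under the step-wise precision-recall curve (distinct thresholds)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise UndefinedMetricError("PR-AUC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # cumulative counts at each distinct threshold
    distinct = np.where(np.diff(s) != 0)[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(1 - y)[cut]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def link_prediction_eval(hidden: np.ndarray, graph, test_pairs,
                         known_pairs, k: int = 10, seed: int = 0) -> LinkPredMetrics:
    """Evaluate phage -> bacterium link recovery from hidden representations.

    Edge score = sigmoid(h_phage . h_bacterium).  ROC/PR use one
    uniformly sampled type-valid non-edge negative per positive;
    Hits@K / MRR rank each positive against all type-valid candidates
    with other known positives filtered out.
    """
    test_pairs = sorted(set(map(tuple, test_pairs)))
    known = set(map(tuple, known_pairs)) | set(test_pairs)
    index = graph.node_index
    phage_ids = [graph.node_ids[i] for i in graph.nodes_of_type("Phage")]
    bact_ids = [graph.node_ids[i] for i in graph.nodes_of_type("Bacteria")]
    if not test_pairs:
        raise UndefinedMetricError("no test pairs to evaluate")
    bact_idx = np.array([index[b] for b in bact_ids], dtype=np.intp)

    def score(pid: str, bact_rows: np.ndarray) -> np.ndarray:
        return expit(hidden[bact_rows] @ hidden[index[pid]])

    rng = np.random.default_rng(seed)
    pos_scores, neg_scores = [], []
    for pid, bid in test_pairs:
        pos_scores.append(float(score(pid, np.array([index[bid]]))[0]))
        while True:
            np_id = phage_ids[rng.integers(len(phage_ids))]
            nb_id = bact_ids[rng.integers(len(bact_ids))]
            if (np_id, nb_id) not in known:
                neg_scores.append(float(score(np_id, np.array([index[nb_id]]))[0]))
                break
    scores = np.array(pos_scores + neg_scores)
    labels = np.array([1] * len(pos_scores) + [0] * len(neg_scores))
    roc = roc_auc(scores, labels)
    pr = pr_auc(scores, labels)

    ranks = []
    known_by_phage: dict[str, set[str]] = {}
    for p, b in known:
        known_by_phage.setdefault(p, set()).add(b)
    for pid, bid in test_pairs:
        exclude = known_by_phage.get(pid, set()) - {bid}
        cand_ids = [b for b in bact_ids if b not in exclude]
        if len(cand_ids) <= 1:
            logger.warning("phage %s has no candidate negatives; skipped", pid)
            continue
        rows = np.array([index[b] for b in cand_ids], dtype=np.intp)
        sc = score(pid, rows)
        target = cand_ids.index(bid)
        ranks.append(1 + int((sc > sc[target]).sum()))
    if not ranks:
        raise UndefinedMetricError("no rankable test pairs")
    ranks = np.array(ranks)
    return LinkPredMetrics(
        roc_auc=roc, pr_auc=pr,
        hits_at_k=float((ranks <= k).mean()),
        mrr=float((1.0 / ranks).mean()),
        k=k, n_positives=len(test_pairs))


def mrr_from_ranks(ranks) -> float:
    ranks = np.asarray(ranks, dtype=float)
    return float((1.0 / ranks).mean())


def hits_at_k(ranks, k: int) -> float:
    ranks = np.asarray(ranks, dtype=float)
    return float((ranks <= k).mean())


def site_disease_scores(disease_prob: np.ndarray, graph) -> dict[str, float]:
    """Mean predicted disease probability over viruses enriched per site.

    A virus enriched at several sites contributes to each of their
    means; sites with no enriched viruses are omitted with a warning.
    """
    virus_types = ("Virus", "Phage")
    by_site: dict[str, list[float]] = {s: [] for s in graph.sites}
    index = graph.node_index
    types = graph.node_types
    for s, r, d in graph.edges:
        if r != "ENRICHED_AT":
            continue
        i = index[s]
        if types[i] not in virus_types:
            continue
        site = d[len("SITE:"):]
        if site in by_site:
            by_site[site].append(float(disease_prob[i]))
    out = {}
    for site, vals in by_site.items():
        if not vals:
            logger.warning("site %r has no enriched viruses; omitted", site)
            continue
        out[site] = float(np.mean(vals))
    return out


def convergence_improvement(fast_epochs: float, slow_epochs: float) -> float:
    """Percentage reduction in epochs-to-convergence of the faster model."""
    if slow_epochs <= 0:
        raise ValueError("slow_epochs must be positive")
    return 100.0 * (slow_epochs - fast_epochs) / slow_epochs
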
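"""Knowledge-graph construction from multi-kingdom microbiome tables.

Parses taxon tables, infers co-occurrence edges by thresholded Spearman
correlation over per-sample abundance profiles, and assembles a typed
graph with per-node feature vectors and disease labels.

Node types: ``Bacteria``, ``Virus``, ``Phage``, ``Site`` plus auxiliary
``Lineage`` nodes used by IS_A taxonomy chains.  Relations: phage ->
bacterium ``INFECTS``; microbe -> site ``ENRICHED_AT``; taxon -> parent
``IS_A``; and symmetric ``CO_OCCURS`` pairs stored in both directions.
The ``disease`` label is defined by enrichment at the "Dental Plaque"
site.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RELATIONS = ("INFECTS", "ENRICHED_AT", "IS_A", "CO_OCCURS")
DISEASE_SITE = "Dental Plaque"
DISEASE, HEALTH = "disease", "health"
_LINEAGE_PREFIX = "LINEAGE:"


class FormatError(ValueError):
    """A required column or structural element of the input is missing."""


class ValidationError(ValueError):
    """Input values violate a record invariant."""


class LabelingError(ValueError):
    """Disease labeling cannot proceed (no disease-defining site node)."""


@dataclass
class MicrobeRecord:
    """One taxon row: identity, lineage, genomic traits and abundances."""

    taxon_id: str
    name: str
    kingdom: str
    is_phage: bool
    predicted_host: str | None
    lineage: tuple[str, ...]
    genome_size: float
    gc_content: float
    site_abundance: dict[str, float]
    mean_abundance: float
    enriched_sites: frozenset[str]

    def __post_init__(self):
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValidationError(
                f"{self.taxon_id}: GC content {self.gc_content} outside [0, 1]")
        if self.mean_abundance < 0 or any(v < 0 for v in self.site_abundance.values()):
            raise ValidationError(f"{self.taxon_id}: negative abundance")
        if self.is_phage and self.kingdom != "Virus":
            raise ValidationError(f"{self.taxon_id}: phage flag on non-virus record")
        if self.predicted_host is not None and not self.is_phage:
            raise ValidationError(
                f"{self.taxon_id}: predicted host on a non-phage record")


@dataclass
class MicrobeTable:
    """Parsed taxon records plus the taxa x samples abundance matrix."""

    records: list[MicrobeRecord]
    sample_matrix: np.ndarray
    sample_names: list[str]
    sites: tuple[str, ...]

    def __post_init__(self):
        ids = [r.taxon_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        if self.sample_matrix.shape[0] != len(self.records):
            raise ValidationError("sample matrix rows do not match record count")
        if np.any(self.sample_matrix < 0):
            raise ValidationError("negative abundance in sample matrix")

    @property
    def taxon_ids(self) -> list[str]:
        return [r.taxon_id for r in self.records]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Render the table as the two CSV frames of the file contract."""
        rows = []
        for r in self.records:
            row = {
                "Taxon": r.taxon_id,
                "Kingdom": r.kingdom,
                "Is_Phage": int(r.is_phage),
                "Predicted_host": r.predicted_host or "",
                "Lineage": ";".join(r.lineage),
                "Genome_Size_bp": r.genome_size,
                "GC_Content": r.gc_content,
                "Mean_Abundance": r.mean_abundance,
            }
            for site in self.sites:
                row[f"Abund_{site}"] = r.site_abundance.get(site, 0.0)
            for site in self.sites:
                row[f"Enriched_{site}"] = int(site in r.enriched_sites)
            rows.append(row)
        table_df = pd.DataFrame(rows)
        samples_df = pd.DataFrame(
            self.sample_matrix, columns=self.sample_names)
        samples_df.insert(0, "Taxon", self.taxon_ids)
        return table_df, samples_df


@dataclass(frozen=True)
class CoOccurrenceEdge:
    """Significant unordered co-occurrence pair (lexicographic order)."""

    taxon_a: str
    taxon_b: str
    rho: float
    p_value: float


def parse_microbe_table(table_path, samples_path) -> MicrobeTable:
    """Read the taxon CSV and companion samples CSV into a MicrobeTable."""
    df = pd.read_csv(table_path)
    for col in ("Taxon", "Kingdom"):
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}' in {table_path}")
    sites = tuple(c[len("Abund_"):] for c in df.columns if c.startswith("Abund_"))

    records = []
    for _, row in df.iterrows():
        host = row.get("Predicted_host")
        if pd.isna(host) or host == "":
            host = None
        lineage = tuple(str(row.get("Lineage", "")).split(";")) if pd.notna(row.get("Lineage")) else ()
        enriched = frozenset(
            s for s in sites if int(row.get(f"Enriched_{s}", 0)) == 1)
        records.append(MicrobeRecord(
            taxon_id=str(row["Taxon"]),
            name=str(row["Taxon"]),
            kingdom=str(row["Kingdom"]),
            is_phage=bool(int(row.get("Is_Phage", 0))),
            predicted_host=host,
            lineage=lineage,
            genome_size=float(row.get("Genome_Size_bp", 0.0)),
            gc_content=float(row.get("GC_Content", 0.0)),
            site_abundance={s: float(row.get(f"Abund_{s}", 0.0)) for s in sites},
            mean_abundance=float(row.get("Mean_Abundance", 0.0)),
            enriched_sites=enriched,
        ))

    sdf = pd.read_csv(samples_path)
    if "Taxon" not in sdf.columns:
        raise FormatError(f"missing required column 'Taxon' in {samples_path}")
    sdf = sdf.set_index("Taxon")
    ids = [r.taxon_id for r in records]
    missing = [i for i in ids if i not in sdf.index]
    if missing:
        raise ValidationError(f"sample matrix missing taxa: {missing[:5]}")
    matrix = sdf.loc[ids].to_numpy(dtype=float)
    return MicrobeTable(records=records, sample_matrix=matrix,
                        sample_names=list(sdf.columns), sites=sites)


def spearman_cooccurrence(sample_matrix: np.ndarray,
                          rho_threshold: float = 0.5,
                          alpha: float = 0.01,
                          taxa: list[str] | None = None) -> list[CoOccurrenceEdge]:
    """All-pairs Spearman screen of the taxa x samples matrix.

    An unordered pair is emitted iff ``|rho| > rho_threshold`` and the
    two-sided p-value from the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` with ``n-2`` degrees of freedom
    is below ``alpha``.  Ties get average ranks; ``|rho| = 1`` is treated
    as ``p = 0``.  Constant rows are skipped with a warning.
    """
    M = np.asarray(sample_matrix, dtype=float)
    n_taxa, n = M.shape
    if n < 4:
        raise ValueError(f"need >= 4 samples for the p-value, got {n}")
    if taxa is None:
        taxa = [str(i) for i in range(n_taxa)]

    ranks = stats.rankdata(M, axis=1)
    sd = ranks.std(axis=1)
    ok = sd > 0
    n_const = int((~ok).sum())
    if n_const:
        logger.warning("skipping %d constant row(s) in co-occurrence screen", n_const)
    idx = np.where(ok)[0]
    if len(idx) < 2:
        return []

    R = np.corrcoef(ranks[idx])
    np.clip(R, -1.0, 1.0, out=R)
    iu, ju = np.triu_indices(len(idx), k=1)
    rho = R[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0 - 1e-15, 0.0, p)

    keep = (np.abs(rho) > rho_threshold) & (p < alpha)
    edges = []
    for a, b, r_, p_ in zip(idx[iu[keep]], idx[ju[keep]], rho[keep], p[keep]):
        ta, tb = sorted((taxa[a], taxa[b]))
        edges.append(CoOccurrenceEdge(ta, tb, float(r_), float(p_)))
    return edges


@dataclass
class KnowledgeGraph:
    """Typed nodes with feature vectors, typed edges, and disease labels.

    ``node_ids`` fixes the (insertion-ordered) node indexing used by all
    downstream tensors.  ``features`` rows align with ``node_ids``; the
    first ``n_numeric_features`` columns are the numeric block that
    feature standardization operates on.
    """

    node_ids: list[str]
    node_types: list[str]
    features: np.ndarray
    n_numeric_features: int
    edges: list[tuple[str, str, str]]  # (src, relation, dst)
    sites: tuple[str, ...]
    relations: tuple[str, ...] = RELATIONS
    labels: dict[str, str] = field(default_factory=dict)
    build_report: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def node_index(self) -> dict[str, int]:
        if not hasattr(self, "_node_index"):
            self._node_index = {nid: i for i, nid in enumerate(self.node_ids)}
        return self._node_index

    def nodes_of_type(self, *types: str) -> list[int]:
        return [i for i, t in enumerate(self.node_types) if t in types]

    def infects_pairs(self) -> set[tuple[str, str]]:
        return {(s, d) for s, r, d in self.edges if r == "INFECTS"}

    def enriched_site_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for s, r, d in self.edges:
            if r == "ENRICHED_AT":
                out.setdefault(s, set()).add(d)
        return out

    def undirected_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (indptr, indices) over the untyped undirected edge set."""
        index = self.node_index
        pairs = set()
        for s, _, d in self.edges:
            a, b = index[s], index[d]
            if a != b:
                pairs.add((a, b))
                pairs.add((b, a))
        if pairs:
            arr = np.array(sorted(pairs), dtype=np.intp)
            counts = np.bincount(arr[:, 0], minlength=self.n_nodes)
            indptr = np.concatenate([[0], np.cumsum(counts)])
            indices = arr[:, 1]
        else:
            indptr = np.zeros(self.n_nodes + 1, dtype=np.intp)
            indices = np.array([], dtype=np.intp)
        return indptr, indices

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        meta = {"n_numeric_features": self.n_numeric_features,
                "sites": list(self.sites), "relations": list(self.relations)}
        with open(outdir / "nodes.tsv", "w") as fh:
            fh.write("#meta\t" + json.dumps(meta) + "\n")
            fh.write("node_id\tnode_type\tlabel\tfeatures\n")
            for i, nid in enumerate(self.node_ids):
                feats = ",".join(repr(float(v)) for v in self.features[i])
                fh.write(f"{nid}\t{self.node_types[i]}\t{self.labels.get(nid, '')}\t{feats}\n")
        with open(outdir / "edges.tsv", "w") as fh:
            fh.write("src\trelation\tdst\n")
            for s, r, d in self.edges:
                fh.write(f"{s}\t{r}\t{d}\n")
        with open(outdir / "build_report.json", "w") as fh:
            json.dump(self.build_report, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, outdir) -> "KnowledgeGraph":
        outdir = Path(outdir)
        node_ids, node_types, labels, feats = [], [], {}, []
        with open(outdir / "nodes.tsv") as fh:
            meta = json.loads(fh.readline().split("\t", 1)[1])
            fh.readline()  # header
            for line in fh:
                nid, ntype, label, fvals = line.rstrip("\n").split("\t")
                node_ids.append(nid)
                node_types.append(ntype)
                if label:
                    labels[nid] = label
                feats.append([float(v) for v in fvals.split(",")])
        edges = []
        with open(outdir / "edges.tsv") as fh:
            fh.readline()
            for line in fh:
                s, r, d = line.rstrip("\n").split("\t")
                edges.append((s, r, d))
        report = {}
        report_path = outdir / "build_report.json"
        if report_path.exists():
            report = json.loads(report_path.read_text())
        return cls(node_ids=node_ids, node_types=node_types,
                   features=np.array(feats), n_numeric_features=meta["n_numeric_features"],
                   edges=edges, sites=tuple(meta["sites"]),
                   relations=tuple(meta["relations"]), labels=labels,
                   build_report=report)


def build_graph(table: MicrobeTable,
                cooccurrence: list[CoOccurrenceEdge],
                exclude_infects: set[tuple[str, str]] | frozenset = frozenset()) -> KnowledgeGraph:
    """Assemble the typed knowledge graph from a parsed table.

    ``exclude_infects`` holds (phage, host) pairs withheld from the graph
    (for link-prediction evaluation); they are counted in the build
    report rather than added.
    """
    sites = table.sites
    kingdoms = sorted({r.lineage[0] if r.lineage else r.kingdom for r in table.records})
    max_depth = max((len(r.lineage) for r in table.records), default=0)
    n_numeric = 3 + len(sites)
    feat_len = n_numeric + len(kingdoms) + max_depth

    node_ids: list[str] = []
    node_types: list[str] = []
    features: list[np.ndarray] = []
    index: dict[str, int] = {}

    def add_node(nid: str, ntype: str, feat: np.ndarray) -> None:
        index[nid] = len(node_ids)
        node_ids.append(nid)
        node_types.append(ntype)
        features.append(feat)

    bacteria_names: dict[str, str] = {}
    for rec in table.records:
        # genome size and abundances are heavy-tailed; log-scale them so the
        # z-scored numeric block is well-conditioned for gradient training
        numeric = [np.log10(rec.genome_size + 1.0), rec.gc_content,
                   np.log(rec.mean_abundance + 1e-9)]
        numeric += [np.log(rec.site_abundance.get(s, 0.0) + 1e-9) for s in sites]
        top = rec.lineage[0] if rec.lineage else rec.kingdom
        onehot = np.zeros(len(kingdoms))
        onehot[kingdoms.index(top)] = 1.0
        feat = np.concatenate([numeric, onehot, np.zeros(max_depth)])
        ntype = "Phage" if rec.is_phage else rec.kingdom
        add_node(rec.taxon_id, ntype, feat)
        if rec.kingdom == "Bacteria":
            bacteria_names[rec.name] = rec.taxon_id
            bacteria_names[rec.taxon_id] = rec.taxon_id

    edges: list[tuple[str, str, str]] = []
    seen_isa: set[tuple[str, str]] = set()
    dropped_hosts = 0
    held_out = 0

    for rec in table.records:
        # taxonomy chain: taxon -> deepest rank -> ... -> top rank
        chain = [rec.taxon_id]
        for depth, rank_name in reversed(list(enumerate(rec.lineage))):
            lin_id = _LINEAGE_PREFIX + rank_name
            if lin_id not in index:
                marker = np.zeros(feat_len)
                marker[n_numeric + len(kingdoms) + depth] = 1.0
                add_node(lin_id, "Lineage", marker)
            chain.append(lin_id)
        for child, parent in zip(chain[:-1], chain[1:]):
            if (child, parent) not in seen_isa:
                seen_isa.add((child, parent))
                edges.append((child, "IS_A", parent))
        for site in sorted(rec.enriched_sites):
            edges.append((rec.taxon_id, "ENRICHED_AT", f"SITE:{site}"))
        if rec.is_phage and rec.predicted_host is not None:
            host_id = bacteria_names.get(rec.predicted_host)
            if host_id is None:
                dropped_hosts += 1
            elif (rec.taxon_id, host_id) in exclude_infects:
                held_out += 1
            else:
                edges.append((rec.taxon_id, "INFECTS", host_id))

    for site in sites:
        add_node(f"SITE:{site}", "Site", np.zeros(feat_len))

    known = set(table.taxon_ids)
    for e in cooccurrence:
        if e.taxon_a not in known or e.taxon_b not in known:
            raise ValidationError(
                f"co-occurrence edge references unknown taxa ({e.taxon_a}, {e.taxon_b})")
        edges.append((e.taxon_a, "CO_OCCURS", e.taxon_b))
        edges.append((e.taxon_b, "CO_OCCURS", e.taxon_a))

    relation_counts: dict[str, int] = {r: 0 for r in RELATIONS}
    for _, r, _ in edges:
        relation_counts[r] += 1
    report = {
        "relation_counts": relation_counts,
        "co_occurs_pairs_unordered": len(cooccurrence),
        "co_occurs_pairs_directed": 2 * len(cooccurrence),
        "dropped_hosts": dropped_hosts,
        "held_out_infects": held_out,
        "n_nodes": len(node_ids),
    }
    graph = KnowledgeGraph(
        node_ids=node_ids, node_types=node_types,
        features=np.vstack(features) if features else np.zeros((0, feat_len)),
        n_numeric_features=n_numeric, edges=edges, sites=sites,
        build_report=report)
    return graph


def assign_disease_labels(graph: KnowledgeGraph,
                          disease_site: str = DISEASE_SITE) -> dict[str, str]:
    """Label microbe nodes: disease iff enriched at the disease site."""
    site_node = f"SITE:{disease_site}"
    if site_node not in graph.node_index:
        raise LabelingError(f"no '{disease_site}' site node in the graph")
    enriched_at_disease = {
        s for s, r, d in graph.edges if r == "ENRICHED_AT" and d == site_node}
    labels = {}
    for nid, ntype in zip(graph.node_ids, graph.node_types):
        if ntype in ("Bacteria", "Virus", "Phage"):
            labels[nid] = DISEASE if nid in enriched_at_disease else HEALTH
    graph.labels = labels
    return labels
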
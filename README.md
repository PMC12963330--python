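# biofilmkg

Relation-aware knowledge-graph learning for phage–host specificity and
disease association in oral-biofilm microbiomes.

The package builds a heterogeneous knowledge graph from a multi-kingdom
microbiome table (Bacteria / Virus / Phage / Site nodes; INFECTS,
ENRICHED_AT, IS_A and CO_OCCURS relations), fuses Node2Vec structural
embeddings with projected raw features through a learned gate, and trains
a lightweight relation-aware graph attention network for disease-node
classification and phage→host link prediction, alongside GAT and GCN
baselines. A seeded synthetic-data generator emulates the statistical
shape of an oral-microbiome survey (four oral sites, dental-plaque
enrichment defining the disease label, latent-factor co-abundance, hub
host bacteria) so the whole pipeline is testable offline.

Everything runs on numpy/scipy; the models are trained with a small
in-repo reverse-mode autodiff engine (`biofilmkg.nn`), so no deep-learning
framework is required.

## Layout

| module | contents |
|---|---|
| `biofilmkg.synth` | synthetic dataset generator + INFECTS holdout |
| `biofilmkg.kg` | table parsing, Spearman co-occurrence screen, graph assembly, disease labels |
| `biofilmkg.node2vec` | biased random walks + numpy skip-gram (SGNS) embeddings |
| `biofilmkg.fusion` | gated fusion of structural and feature views |
| `biofilmkg.models` | relation-aware attention network, GAT and GCN baselines, adjacency normalization, parameter accounting |
| `biofilmkg.train` | stratified splits, z-scoring, class-weighted loss, early-stopped full-batch training |
| `biofilmkg.metrics` | confusion/ROC/PR metrics, Hits@K / MRR link evaluation, site disease scores |
| `biofilmkg.pipeline` | end-to-end experiment wiring |
| `biofilmkg.cli` | `biofilmkg` command-line entry point |

## CLI

A run directory accumulates artifacts stage by stage; a single YAML
config (sections `synth`, `walk`, `train`, `eval`) drives all stages, and
`--seed` overrides every stage seed.

```bash
biofilmkg simulate    --out runs/demo            # microbes.csv samples.csv truth.json
biofilmkg build-graph --out runs/demo            # nodes.tsv edges.tsv build_report.json
biofilmkg embed       --out runs/demo            # embeddings.tsv
biofilmkg train       --out runs/demo --model relgat   # checkpoint + history JSON
biofilmkg evaluate    --out runs/demo --model relgat   # metrics_relgat.json
biofilmkg train       --out runs/demo --model gat
biofilmkg evaluate    --out runs/demo --model gat
biofilmkg report      --out runs/demo            # report.txt comparison
```

Model kinds: `relgat` (relation-aware attention), `gat` (relation-blind
baseline), `gcn`.

### Metrics JSON schema

`metrics_<model>.json` contains:

- `classification`: accuracy, sensitivity, specificity, mcc,
  weighted_precision, weighted_recall, weighted_f1, auc_roc (disease
  classification on the held-out test nodes);
- `confusion`: tp / fn / tn / fp;
- `link_prediction`: roc_auc, pr_auc, hits_at_k, mrr, k, n_positives
  (held-out INFECTS pairs vs sampled type-valid non-edges);
- `site_scores`: mean predicted disease probability per oral site;
- `history`: best/stopped epoch and best validation loss;
- `n_parameters`, `model`, `config_hash`.

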
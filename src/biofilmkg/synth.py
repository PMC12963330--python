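"""Seeded synthetic multi-kingdom oral-microbiome tables.

Generates taxon tables whose statistical shape matches the target
experiment: a few hundred viral taxa over four oral sites, a minority
enriched at dental plaque (the disease-defining niche), dense
co-abundance structure driven by shared latent factors, and phage->host
assignments concentrated on hub bacteria via preferential attachment.

The generative model is log-linear: per-sample abundance is
``exp(base + loadings . factors + site effect + noise)``, which gives
positive abundances and a tunable Spearman co-occurrence density.
Phages inherit their host's latent factor so that held-out infection
links remain learnable from graph context.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .kg import MicrobeRecord, MicrobeTable

DEFAULT_SITES = ("Dental Plaque", "Tongue", "Buccal Mucosa", "Saliva")
DISEASE_SITE = "Dental Plaque"


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SynthConfig:
    n_virus: int = 500
    n_disease_virus: int = 81
    n_bacteria: int = 150
    phage_fraction: float = 0.7
    sites: tuple[str, ...] = DEFAULT_SITES
    n_samples: int = 60
    n_latent_factors: int = 8
    hub_exponent: float = 1.5
    noise_sd: float = 0.7
    enrichment_multiplier: float = 8.0
    seed: int = 42

    def __post_init__(self):
        if self.n_virus <= 0 or self.n_bacteria <= 0 or self.n_samples <= 0 \
                or self.n_latent_factors <= 0:
            raise ConfigurationError("all counts must be positive")
        if self.n_disease_virus < 0 or self.n_disease_virus > self.n_virus:
            raise ConfigurationError(
                f"n_disease_virus={self.n_disease_virus} exceeds n_virus={self.n_virus}")
        if not self.sites:
            raise ConfigurationError("sites must be non-empty")
        if DISEASE_SITE not in self.sites:
            raise ConfigurationError(f"sites must contain '{DISEASE_SITE}'")
        if self.enrichment_multiplier <= 1:
            raise ConfigurationError("enrichment_multiplier must exceed 1")
        if not 0.0 <= self.phage_fraction <= 1.0:
            raise ConfigurationError("phage_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure: infection pairs, labels and latent loadings."""

    infects_pairs: set[tuple[str, str]]
    disease_labels: dict[str, str]
    latent_loadings: np.ndarray
    taxa: list[str]
    config: SynthConfig


def generate_dataset(config: SynthConfig) -> tuple[MicrobeTable, GroundTruth]:
    """Generate a seeded synthetic dataset; identical seed, identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sites = len(cfg.sites)
    dp = cfg.sites.index(DISEASE_SITE)
    other_sites = [i for i in range(n_sites) if i != dp] or [dp]

    virus_ids = [f"V{i:04d}" for i in range(cfg.n_virus)]
    bact_ids = [f"B{i:03d}" for i in range(cfg.n_bacteria)]
    taxa = virus_ids + bact_ids
    n_taxa = len(taxa)

    # lineages (illustrative programmatic names; 3 ranks: kingdom;clade;genus)
    n_bgenus = max(5, cfg.n_bacteria // 5)
    n_vgenus = max(5, cfg.n_virus // 12)
    bact_genus = rng.integers(0, n_bgenus, cfg.n_bacteria)
    virus_genus = rng.integers(0, n_vgenus, cfg.n_virus)

    # phage flags and host assignment by preferential attachment
    n_phage = int(round(cfg.phage_fraction * cfg.n_virus))
    phage_set = set(rng.choice(cfg.n_virus, n_phage, replace=False).tolist())

    k = cfg.n_latent_factors
    bact_factor = rng.integers(0, k, cfg.n_bacteria)
    virus_factor = rng.integers(0, k, cfg.n_virus)

    host_of: dict[int, int] = {}
    host_degree = np.zeros(cfg.n_bacteria)
    for v in rng.permutation(sorted(phage_set)):
        w = (host_degree + 1.0) ** cfg.hub_exponent
        host = int(rng.choice(cfg.n_bacteria, p=w / w.sum()))
        host_of[int(v)] = host
        host_degree[host] += 1
        virus_factor[v] = bact_factor[host]  # phage co-abounds with its host

    # enrichment: disease viruses at dental plaque, everything else elsewhere
    disease_set = set(rng.choice(cfg.n_virus, cfg.n_disease_virus, replace=False).tolist())
    virus_site = np.array([dp if v in disease_set else rng.choice(other_sites)
                           for v in range(cfg.n_virus)])
    bact_site = rng.choice(other_sites, cfg.n_bacteria)
    enr_site = np.concatenate([virus_site, bact_site])

    # loading strength tuned so the default run yields a co-occurrence edge
    # count of the same order as the target experiment (~2e4 unordered pairs)
    strength = 1.4
    factor = np.concatenate([virus_factor, bact_factor])
    loadings = np.zeros((n_taxa, k))
    loadings[np.arange(n_taxa), factor] = strength

    log_base = rng.normal(-4.0, 1.0, n_taxa)
    log_mult = math.log(cfg.enrichment_multiplier)

    jitter = rng.normal(0.0, 0.3, (n_taxa, n_sites))
    site_ab = np.exp(log_base[:, None] + jitter)
    site_ab[np.arange(n_taxa), enr_site] *= cfg.enrichment_multiplier
    mean_ab = site_ab.mean(axis=1)

    sample_site = np.arange(cfg.n_samples) % n_sites
    factor_scores = rng.normal(size=(k, cfg.n_samples))
    noise = rng.normal(0.0, cfg.noise_sd, (n_taxa, cfg.n_samples))
    site_effect = log_mult * (enr_site[:, None] == sample_site[None, :])
    sample_matrix = np.exp(log_base[:, None] + loadings @ factor_scores
                           + site_effect + noise)

    genome = np.concatenate([
        rng.integers(5_000, 200_000, cfg.n_virus),
        rng.integers(1_500_000, 6_000_000, cfg.n_bacteria),
    ]).astype(float)
    gc = rng.uniform(0.25, 0.75, n_taxa)

    records: list[MicrobeRecord] = []
    for v in range(cfg.n_virus):
        g = virus_genus[v]
        records.append(MicrobeRecord(
            taxon_id=virus_ids[v], name=virus_ids[v], kingdom="Virus",
            is_phage=v in phage_set,
            predicted_host=bact_ids[host_of[v]] if v in host_of else None,
            lineage=("Viruses", f"VirClade{g % 5}", f"VirGenus{g:02d}"),
            genome_size=genome[v], gc_content=gc[v],
            site_abundance={s: site_ab[v, j] for j, s in enumerate(cfg.sites)},
            mean_abundance=mean_ab[v],
            enriched_sites=frozenset({cfg.sites[virus_site[v]]}),
        ))
    for b in range(cfg.n_bacteria):
        t = cfg.n_virus + b
        g = bact_genus[b]
        records.append(MicrobeRecord(
            taxon_id=bact_ids[b], name=bact_ids[b], kingdom="Bacteria",
            is_phage=False, predicted_host=None,
            lineage=("Bacteria", f"BactPhylum{g % 4}", f"BactGenus{g:02d}"),
            genome_size=genome[t], gc_content=gc[t],
            site_abundance={s: site_ab[t, j] for j, s in enumerate(cfg.sites)},
            mean_abundance=mean_ab[t],
            enriched_sites=frozenset({cfg.sites[bact_site[b]]}),
        ))

    table = MicrobeTable(
        records=records, sample_matrix=sample_matrix,
        sample_names=[f"S{j:03d}" for j in range(cfg.n_samples)],
        sites=cfg.sites)
    truth = GroundTruth(
        infects_pairs={(virus_ids[v], bact_ids[h]) for v, h in host_of.items()},
        disease_labels={tid: ("disease" if i < cfg.n_virus and i in disease_set else "health")
                        for i, tid in enumerate(taxa)},
        latent_loadings=loadings, taxa=taxa, config=cfg)
    return table, truth


def hold_out_infects(truth: GroundTruth, fraction: float,
                     seed: int) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Seeded disjoint train/test partition of the planted infection pairs.

    Test share is ``round(fraction * n)`` with round-half-up.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    pairs = sorted(truth.infects_pairs)
    n_test = int(math.floor(fraction * len(pairs) + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    test = {pairs[i] for i in order[:n_test]}
    train = {pairs[i] for i in order[n_test:]}
    return train, test


def write_dataset(table: MicrobeTable, truth: GroundTruth, outdir) -> None:
    """Write microbes.csv, samples.csv and truth.json to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_df, samples_df = table.to_frames()
    table_df.to_csv(outdir / "microbes.csv", index=False)
    samples_df.to_csv(outdir / "samples.csv", index=False)
    payload = {
        "infects_pairs": sorted(list(p) for p in truth.infects_pairs),
        "disease_labels": truth.disease_labels,
        "config": asdict(truth.config),
    }
    payload["config"]["sites"] = list(truth.config.sites)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_truth(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    payload["infects_pairs"] = {tuple(p) for p in payload["infects_pairs"]}
    return payload
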
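"""Synthetic cohort generator.

No public per-gene compiled dataset accompanies the prioritization
method, so development and testing run on synthetic cohorts that
reproduce the statistical structure the analysis assumes:

* a ~1:40 pain / non-pain label imbalance (100 positives in the default
  4,100-gene cohort);
* positives planted preferentially on hubs of a scale-free
  (preferential-attachment) interaction graph, so degree, stress and
  radiality separate the classes;
* a GO vocabulary in which a designated subset of terms is annotated to
  positives at elevated odds, plus one decoy term named
  "response to pain signal" that exists solely to exercise the
  vocabulary leakage guard;
* per-(tissue, species) omics datasets in which a random half of the
  positives carry a log2 fold-change shift with small FDR, against a
  noise background.

Everything derives from one master seed (fanned out to the component
simulators by fixed offsets), and all outputs round-trip through the
package's readers. The truth record (planted positives, informative
terms, effect carriers) makes recovery experiments scoreable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .enrichment import GeneSet, write_gmt
from .features import DatasetMeta

__all__ = ["SimConfig", "SyntheticCohort", "simulate_graph", "plant_labels",
           "simulate_go", "simulate_omics", "simulate_validation_set", "generate"]

DECOY_TERM = ("GO:DECOY", "response to pain signal")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort (defaults are the
    conditions every test and the acceptance run use)."""

    n_genes: int = 4100
    pos_fraction: float = 1 / 41  # P/NP = 1/40
    seed: int = 0
    graph_attachment: int = 3
    hub_bias: float = 2.0
    n_go_terms: int = 300
    n_informative_terms: int = 20
    go_enrichment_odds: float = 4.0
    n_omics_groups: int = 6
    datasets_per_group: int = 2
    lfc_effect: float = 1.0
    lfc_noise_sd: float = 1.0
    frac_significant_background: float = 0.05
    validation_overlap: float = 0.5

    def __post_init__(self):
        if not 0 < self.pos_fraction < 1:
            raise ValueError(f"pos_fraction must lie in (0, 1), got {self.pos_fraction}")
        if not 0 <= self.validation_overlap <= 1:
            raise ValueError("validation_overlap must lie in [0, 1]")
        for name in ("n_genes", "graph_attachment", "n_go_terms", "n_omics_groups"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes <= self.graph_attachment:
            raise ValueError("n_genes must exceed graph_attachment")


@dataclass
class SyntheticCohort:
    config: SimConfig
    table: pd.DataFrame  # raw gene table (indexed by gene_id)
    meta: dict  # omics column -> DatasetMeta
    graph: nx.Graph
    labels: pd.Series  # 1 = planted pain gene
    go_annotations: dict  # gene -> [(term_id, term_name), ...]
    validation_set: GeneSet  # synthetic HPGDB stand-in
    truth: dict = field(default_factory=dict)

    @property
    def positives(self) -> frozenset:
        return frozenset(self.labels.index[self.labels == 1])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def simulate_graph(cfg: SimConfig) -> nx.Graph:
    """Connected preferential-attachment graph over all genes."""
    g = nx.barabasi_albert_graph(cfg.n_genes, cfg.graph_attachment,
                                 seed=cfg.seed + 1)
    ids = _gene_ids(cfg.n_genes)
    return nx.relabel_nodes(g, dict(enumerate(ids)))


def plant_labels(g: nx.Graph, cfg: SimConfig):
    """Sample positives without replacement with probability ~ degree^hub_bias."""
    rng = np.random.default_rng(cfg.seed + 2)
    genes = sorted(g.nodes)
    deg = np.array([g.degree(v) for v in genes], dtype=float)
    w = deg ** cfg.hub_bias
    w = w / w.sum()
    n_pos = int(round(cfg.n_genes * cfg.pos_fraction))
    pos_idx = rng.choice(len(genes), size=n_pos, replace=False, p=w)
    positives = {genes[i] for i in pos_idx}
    labels = pd.Series({v: int(v in positives) for v in genes}, name="label")
    truth = {"positives": sorted(positives)}
    return labels, truth


def simulate_go(labels: pd.Series, cfg: SimConfig):
    """Assign GO terms; informative terms favour positives at elevated odds.

    Every cohort also carries the decoy term "response to pain signal"
    (given mostly to positives) so the feature-engineering guard that
    bans pain-named terms is exercised by realistic bait.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    genes = sorted(labels.index)
    is_pos = labels.loc[genes].to_numpy() == 1

    terms = [(f"GO:{7000000 + i:07d}", f"synthetic process {i}")
             for i in range(cfg.n_go_terms)]
    informative = terms[: cfg.n_informative_terms]
    base_rate = rng.uniform(0.01, 0.15, size=cfg.n_go_terms)

    annotations: dict[str, list] = {g: [] for g in genes}
    for (term_id, term_name), q in zip(terms, base_rate):
        odds = cfg.go_enrichment_odds if (term_id, term_name) in informative else 1.0
        p_pos = q * odds / (1 - q + q * odds)
        p = np.where(is_pos, p_pos, q)
        hits = rng.random(len(genes)) < p
        for g, h in zip(genes, hits):
            if h:
                annotations[g].append((term_id, term_name))
    # decoy: heavily label-correlated, must be excluded downstream
    decoy_p = np.where(is_pos, 0.8, 0.02)
    for g, h in zip(genes, rng.random(len(genes)) < decoy_p):
        if h:
            annotations[g].append(DECOY_TERM)
    truth = {"informative_terms": [t for t, _ in informative],
             "decoy_term": DECOY_TERM[0]}
    return annotations, truth


def simulate_omics(labels: pd.Series, cfg: SimConfig):
    """Per-group LFC/FDR/TPM columns with effects planted in positives.

    Each (tissue, species) group gets ``datasets_per_group`` LFC+FDR
    pairs and one TPM column. Within a group, a random half of the
    positives are effect carriers: their LFC is shifted by
    ``lfc_effect`` and their FDR is significant (< 0.05); a
    ``frac_significant_background`` fraction of all other genes is also
    significant, so zeroing by FDR leaves realistic background noise.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    genes = sorted(labels.index)
    n = len(genes)
    pos_idx = np.where(labels.loc[genes].to_numpy() == 1)[0]

    tissues = ["DRG", "skin", "spinal_cord", "sciatic_nerve", "iPSC", "DRG_glia"]
    species = ["mouse", "human", "rat"]
    groups = [(tissues[i % len(tissues)], species[i % len(species)])
              for i in range(cfg.n_omics_groups)]

    cols: dict[str, np.ndarray] = {}
    meta: dict[str, DatasetMeta] = {}
    carriers: dict[str, list[str]] = {}
    for gi, (tissue, sp) in enumerate(groups):
        chosen = rng.choice(pos_idx, size=max(len(pos_idx) // 2, 1), replace=False)
        carrier_mask = np.zeros(n, bool)
        carrier_mask[chosen] = True
        carriers[f"{tissue}_{sp}"] = [genes[i] for i in sorted(chosen)]
        for d in range(cfg.datasets_per_group):
            lfc_col = f"LFC_{tissue}_{sp}_{d}"
            fdr_col = f"FDR_{tissue}_{sp}_{d}"
            lfc = rng.normal(0.0, cfg.lfc_noise_sd, size=n)
            lfc[carrier_mask] += cfg.lfc_effect
            fdr = rng.uniform(0.05, 1.0, size=n)
            sig_bg = rng.random(n) < cfg.frac_significant_background
            fdr[sig_bg] = rng.uniform(0.0, 0.05, size=int(sig_bg.sum()))
            if cfg.lfc_effect != 0:
                # a DE analysis flags carriers because their expression
                # really changed; with no effect they are background
                fdr[carrier_mask] = rng.uniform(0.0, 0.05,
                                                size=int(carrier_mask.sum()))
            cols[lfc_col] = lfc
            cols[fdr_col] = fdr
            meta[lfc_col] = DatasetMeta(tissue, sp, "transcriptome", "LFC", fdr_col)
            meta[fdr_col] = DatasetMeta(tissue, sp, "transcriptome", "FDR")
        tpm_col = f"TPM_{tissue}_{sp}"
        cols[tpm_col] = np.exp(rng.normal(1.0, 1.2, size=n))
        meta[tpm_col] = DatasetMeta(tissue, sp, "transcriptome", "TPM")
    omics = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return omics, meta, {"effect_carriers": carriers}


def simulate_validation_set(labels: pd.Series, g: nx.Graph, cfg: SimConfig) -> GeneSet:
    """Synthetic external validation set (HPGDB analogue).

    About twice the positive count: ``validation_overlap`` of it drawn
    from planted positives, the rest from hub-weighted negatives (the
    "true but unlabelled" analogues a GWAS catalogue would contain).
    """
    rng = np.random.default_rng(cfg.seed + 5)
    genes = sorted(labels.index)
    pos = [v for v in genes if labels[v] == 1]
    neg = [v for v in genes if labels[v] == 0]
    size = 2 * len(pos)
    n_from_pos = min(int(round(cfg.validation_overlap * size)), len(pos))
    n_from_neg = size - int(round(cfg.validation_overlap * size))
    chosen = list(rng.choice(pos, size=n_from_pos, replace=False))
    if n_from_neg:
        deg = np.array([g.degree(v) for v in neg], dtype=float)
        w = deg ** cfg.hub_bias
        w = w / w.sum()
        chosen += list(rng.choice(neg, size=min(n_from_neg, len(neg)),
                                  replace=False, p=w))
    return GeneSet("synthetic_HPGDB",
                   "synthetic external validation set (hub-weighted)",
                   frozenset(chosen))


def _genomic_features(genes: list[str], cfg: SimConfig) -> pd.DataFrame:
    """Uninformative genomic covariates: the cohort plants signal only
    in topology, GO and omics."""
    rng = np.random.default_rng(cfg.seed + 6)
    compartments = ["cytosol", "membrane", "mitochondrion", "nucleus", "secreted"]
    tissues = ["DRG", "brain", "liver", "muscle", "skin"]
    chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    return pd.DataFrame(
        {
            "cellular_compartment": rng.choice(compartments, size=len(genes)),
            "tissue": rng.choice(tissues, size=len(genes)),
            "chromosome_name": rng.choice(chroms, size=len(genes)),
            "gc_content": np.clip(rng.normal(41.0, 5.0, size=len(genes)), 25, 70),
            "conservation_score": rng.beta(2.0, 2.0, size=len(genes)),
        },
        index=pd.Index(genes, name="gene_id"),
    )


def generate(cfg: SimConfig, outdir: str | Path | None = None) -> SyntheticCohort:
    """Compose all simulators under the master seed; optionally write
    every standard-format file (feature TSV + YAML sidecar, GO TSV,
    edge list, labels TSV, GMT, truth JSON)."""
    g = simulate_graph(cfg)
    labels, truth = plant_labels(g, cfg)
    annotations, go_truth = simulate_go(labels, cfg)
    omics, meta, omics_truth = simulate_omics(labels, cfg)
    validation = simulate_validation_set(labels, g, cfg)
    truth.update(go_truth)
    truth.update(omics_truth)
    truth["validation_overlap_members"] = sorted(
        validation.members & frozenset(labels.index[labels == 1])
    )

    genes = sorted(labels.index)
    table = pd.concat([_genomic_features(genes, cfg), omics.loc[genes]], axis=1)
    cohort = SyntheticCohort(cfg, table, meta, g, labels.loc[genes],
                             annotations, validation, truth)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(outdir / "features.tsv", sep="\t", float_format="%.8g")
    sidecar = {
        col: {k: v for k, v in asdict(m).items() if v is not None}
        for col, m in sorted(cohort.meta.items())
    }
    with open(outdir / "features.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    with open(outdir / "go_annotations.tsv", "w") as fh:
        for gene in sorted(cohort.go_annotations):
            for term_id, term_name in cohort.go_annotations[gene]:
                fh.write(f"{gene}\t{term_id}|{term_name}\n")
    with open(outdir / "edges.tsv", "w") as fh:
        fh.write("protein1\tprotein2\n")
        for a, b in sorted(tuple(sorted(e)) for e in cohort.graph.edges):
            fh.write(f"{a}\t{b}\n")
    cohort.labels.rename("label").to_csv(outdir / "labels.tsv", sep="\t",
                                         index_label="gene_id")
    write_gmt([cohort.validation_set], outdir / "validation.gmt")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
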
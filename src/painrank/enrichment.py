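"""Pain-score ranking and enrichment-based validation.

The fitted ensemble assigns every gene a class-1 probability — its pain
score — and the genome-wide ranking is validated against independent
gene sets (for example a synthetic stand-in for the Human Pain Genetics
Database) in two ways:

* a running-sum enrichment score (classic unweighted Kolmogorov-Smirnov
  walk: +1/|hits| at set members, -1/|misses| elsewhere; ES is the
  signed extremum) with a gene-label permutation null and the add-one
  p estimator, and
* hypergeometric over-representation of annotation terms among the top
  and bottom deciles of the ranking, Benjamini-Hochberg adjusted.

Because validation sets can share members with the training labels, a
leakage-removal step subtracts the training positives from a set before
enrichment; results are reported with and without removal side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PainScoreTable",
    "GeneSet",
    "EnrichmentResult",
    "ORAResult",
    "rank_genes",
    "remove_leakage",
    "gsea_enrichment",
    "ora_decile",
    "validate_against_sets",
    "read_gmt",
    "write_gmt",
]


@dataclass
class PainScoreTable:
    """Genes ranked by descending pain score; ties break by gene id."""

    table: pd.DataFrame  # columns gene_id, pain_score, rank

    @property
    def genes(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PainScoreTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    p_perm: float
    n_perm: int
    n_hits: int
    leading_edge: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class ORAResult:
    term: str
    k: int  # hits in selection
    K: int  # term size in universe
    n: int  # selection size
    N: int  # universe size
    p: float
    p_adj: float


def rank_genes(scores) -> PainScoreTable:
    """Rank a gene -> probability map by descending score.

    Ranks are 1..N; equal scores order by gene identifier so the table
    is invariant to input order.
    """
    s = pd.Series(scores, dtype=float)
    if s.empty:
        raise ValueError("no scores supplied")
    if ((s < 0) | (s > 1)).any() or s.isna().any():
        bad = s[(s < 0) | (s > 1) | s.isna()].index[0]
        raise ValueError(f"score for {bad!r} outside [0, 1]")
    df = (
        s.rename("pain_score").rename_axis("gene_id").reset_index()
        .sort_values(["pain_score", "gene_id"], ascending=[False, True],
                     kind="stable")
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return PainScoreTable(df)


def remove_leakage(s: GeneSet, training_positives) -> GeneSet:
    """Subtract training-labelled positives from a validation set."""
    remaining = s.members - frozenset(training_positives)
    if not remaining:
        raise ValueError(
            f"gene set {s.name!r} is fully contained in the training positives; "
            "nothing left to validate against"
        )
    removed = len(s.members) - len(remaining)
    return GeneSet(s.name, f"{s.description} (leakage-removed: {removed})", remaining)


def _es_from_positions(pos: np.ndarray, n: int, k: int):
    """Signed running-sum extremum from sorted 0-based hit positions.

    Works on a (k,) vector or an (r, k) matrix of r permutations.
    """
    pos = np.atleast_2d(pos)
    j = np.arange(1, k + 1)
    miss = n - k
    after = j / k - (pos - j + 1) / miss
    before = (j - 1) / k - (pos - j + 1) / miss
    pos_dev = np.maximum(after.max(axis=1), 0.0)
    neg_dev = np.minimum(before.min(axis=1), 0.0)
    # |peak| ties break toward the positive deviation (tolerance covers
    # the rounding asymmetry of the two running-sum expressions)
    es = np.where(pos_dev >= -neg_dev - 1e-12, pos_dev, neg_dev)
    return es, after


def gsea_enrichment(r: PainScoreTable, s: GeneSet, n_perm: int = 1000,
                    seed: int = 0, weighting_exponent: float = 0.0) -> EnrichmentResult:
    """Running-sum enrichment of a gene set in the pain-score ranking.

    ``weighting_exponent=0`` gives the classic unweighted KS statistic
    (rank-order only); ``1`` weights hit increments by |score|. The
    permutation null shuffles set membership over the ranking universe;
    p = (1 + #{|ES*| >= |ES|}) / (n_perm + 1).
    """
    genes = np.asarray(r.genes)
    n = len(genes)
    hit_mask = np.isin(genes, list(s.members))
    k = int(hit_mask.sum())
    if k < 2:
        raise ValueError(f"gene set {s.name!r} has {k} genes in the ranking; need >= 2")
    if k == n:
        raise ValueError(f"gene set {s.name!r} covers the whole universe; ES undefined")

    rng = np.random.default_rng(seed)
    if weighting_exponent == 0.0:
        positions = np.where(hit_mask)[0]
        es_arr, after = _es_from_positions(positions, n, k)
        es = float(es_arr[0])
        if es > 0:
            stop = positions[int(np.argmax(after[0]))]
            leading = frozenset(genes[positions[positions <= stop]])
        else:
            j = np.arange(1, k + 1)
            before = (j - 1) / k - (positions - j + 1) / (n - k)
            start = positions[int(np.argmin(before))]
            leading = frozenset(genes[positions[positions >= start]])
        # permutation null: uniformly random hit positions, vectorized
        perm_pos = np.sort(
            rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)[:, :k], axis=1
        )
        perm_es, _ = _es_from_positions(perm_pos, n, k)
    else:
        scores = r.table.sort_values("rank")["pain_score"].to_numpy()
        es, leading = _weighted_es(genes, scores, hit_mask, weighting_exponent)
        perm_es = np.empty(n_perm)
        for i in range(n_perm):
            perm_mask = np.zeros(n, bool)
            perm_mask[rng.choice(n, size=k, replace=False)] = True
            perm_es[i], _ = _weighted_es(genes, scores, perm_mask, weighting_exponent)

    p = (1 + int(np.sum(np.abs(perm_es) >= abs(es) - 1e-12))) / (n_perm + 1)
    return EnrichmentResult(es=float(es), p_perm=float(p), n_perm=n_perm,
                            n_hits=k, leading_edge=leading)


def _weighted_es(genes, scores, hit_mask, exponent):
    w = np.abs(scores) ** exponent
    w_hit = np.where(hit_mask, w, 0.0)
    denom_hit = w_hit.sum()
    if denom_hit == 0:
        raise ValueError("all hit weights are zero under the weighted statistic")
    inc = np.where(hit_mask, w_hit / denom_hit, -1.0 / (len(genes) - hit_mask.sum()))
    walk = np.cumsum(inc)
    i_ext = int(np.argmax(np.abs(walk)))
    es = float(walk[i_ext])
    hits = np.where(hit_mask)[0]
    leading = frozenset(genes[hits[hits <= i_ext]]) if es > 0 else frozenset(
        genes[hits[hits >= i_ext]]
    )
    return es, leading


def ora_decile(r: PainScoreTable, annotations: dict, which: str = "top",
               fraction: float = 0.10) -> list[ORAResult]:
    """Hypergeometric over-representation of terms in a ranking decile.

    ``annotations`` maps gene -> iterable of term identifiers. The
    selection is the top (or bottom) ``ceil(fraction * N)`` ranked
    genes; per-term upper-tail hypergeometric p-values are BH-adjusted
    across all tested terms.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must lie in (0, 0.5], got {fraction}")
    if which not in ("top", "bottom"):
        raise ValueError(f"which must be 'top' or 'bottom', got {which!r}")
    ranked = r.table.sort_values("rank")["gene_id"].tolist()
    n_sel = int(np.ceil(fraction * len(ranked)))
    selection = set(ranked[:n_sel] if which == "top" else ranked[-n_sel:])

    universe = [g for g in ranked if g in annotations]
    if not universe:
        raise ValueError("annotations cover no ranked gene")
    term_members: dict[str, set] = {}
    for g in universe:
        for t in annotations[g]:
            term_members.setdefault(t, set()).add(g)

    N = len(ranked)
    rows = []
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        k = len(members & selection)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_sel))
        rows.append((term, k, K, p))
    p_adj = multipletests([p for *_, p in rows], method="fdr_bh")[1]
    return [
        ORAResult(term=t, k=k, K=K, n=n_sel, N=N, p=p, p_adj=float(pa))
        for (t, k, K, p), pa in zip(rows, p_adj)
    ]


def validate_against_sets(r: PainScoreTable, sets, training_positives,
                          n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Enrichment of each set with and without leakage removal.

    Returns one row per set with ES and permutation p for the full set
    and for the set minus training positives; the leakage-removed half
    is NaN when removal empties the set.
    """
    rows = []
    for i, s in enumerate(sets):
        full = gsea_enrichment(r, s, n_perm, seed + i)
        try:
            cleaned_set = remove_leakage(s, training_positives)
            cleaned = gsea_enrichment(r, cleaned_set, n_perm, seed + i)
            es_c, p_c, n_c = cleaned.es, cleaned.p_perm, cleaned.n_hits
        except ValueError:
            es_c, p_c, n_c = np.nan, np.nan, 0
        rows.append({
            "set": s.name, "n_hits": full.n_hits, "es": full.es,
            "p_perm": full.p_perm, "n_hits_noleak": n_c,
            "es_noleak": es_c, "p_perm_noleak": p_c,
        })
    return pd.DataFrame(rows)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: name <tab> description <tab> member1 <tab> member2 ..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], parts[1], frozenset(parts[2:])))
    return sets


def write_gmt(sets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")
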
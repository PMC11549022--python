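"""Gene x feature matrix construction.

Turns raw per-gene annotations (categorical genomic features, GC and
conservation scores, GO term sets, per-dataset log-fold-change / FDR /
TPM columns) plus network topology profiles into the scaled numeric
matrix the classifiers train on.

Leakage is the central design constraint:

* GO terms whose *name* contains "pain" are excluded from the
  vocabulary outright — they would encode the label.
* The TF-IDF/PCA projection of GO terms and the min-max scaler are both
  fitted on training genes only and then applied to all genes, so
  nothing about the validation split can move a transform parameter.

Numeric conventions: missing omics values count as "not detected" and
impute to 0 before scaling; composite log-fold-changes zero out entries
that are not significant at FDR < 0.05 before averaging within a
(tissue, species) dataset group; of any feature pair with |r| >= 0.75
the lower-variance member is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.model_selection import train_test_split

__all__ = [
    "DatasetMeta",
    "FeatureMatrix",
    "encode_categoricals",
    "GoFeaturizer",
    "composite_lfc",
    "correlation_filter",
    "SymmetricMinMaxScaler",
    "split_stratified",
    "assemble_features",
    "read_feature_table",
    "read_go_annotations",
    "write_feature_matrix",
    "read_feature_matrix",
]

CATEGORICAL_FEATURES = ["cellular_compartment", "tissue", "chromosome_name"]


@dataclass(frozen=True)
class DatasetMeta:
    """Provenance tag for one omics column."""

    tissue: str
    species: str
    modality: str  # transcriptome / translatome / proteome
    measure: str  # LFC / TPM / FDR
    fdr_column: str | None = None  # partner FDR column, for LFC columns


@dataclass
class FeatureMatrix:
    """Genes x numeric features plus labels and a provenance log."""

    X: pd.DataFrame
    y: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X.index.name = "gene_id"
        if not self.X.index.equals(self.y.index):
            self.y = self.y.reindex(self.X.index)
        if self.X.columns.duplicated().any():
            dupes = self.X.columns[self.X.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")

    @property
    def genes(self) -> pd.Index:
        return self.X.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset_features(self, names) -> "FeatureMatrix":
        return FeatureMatrix(self.X[list(names)].copy(), self.y.copy(), dict(self.provenance))

    def subset_genes(self, genes) -> "FeatureMatrix":
        return FeatureMatrix(self.X.loc[genes].copy(), self.y.loc[genes].copy(), dict(self.provenance))


def encode_categoricals(table: pd.DataFrame, columns=None):
    """Ordinal-encode categorical columns with codes by sorted label order.

    Returns ``(codes, decode_maps)``; ``decode_maps[col][code] = label``.
    Labels unseen at fit time are mapped to the reserved code
    ``len(categories)`` by :func:`apply_categorical_codes`.
    """
    columns = list(columns) if columns is not None else [
        c for c in CATEGORICAL_FEATURES if c in table.columns
    ]
    codes = pd.DataFrame(index=table.index)
    decode: dict[str, dict[int, str]] = {}
    for col in columns:
        labels = sorted(table[col].dropna().astype(str).unique())
        mapping = {lab: i for i, lab in enumerate(labels)}
        reserved = len(labels)
        codes[col] = [
            mapping.get(str(v), reserved) if pd.notna(v) else reserved
            for v in table[col]
        ]
        decode[col] = {i: lab for lab, i in mapping.items()}
    return codes, decode


class GoFeaturizer:
    """TF-IDF + PCA projection of GO term sets into GO1..GOk features.

    The vocabulary keeps terms annotated to fewer than
    ``max_prevalence`` of the fit genes and drops any term whose name
    contains ``exclude_substring`` (case-insensitive). TF-IDF uses the
    smoothed inverse document frequency ln((1+N)/(1+df)) + 1 with L2
    row normalization; the PCA basis is fitted on the same genes.
    """

    def __init__(self, n_components: int = 2, max_prevalence: float = 0.2,
                 exclude_substring: str = "pain"):
        self.n_components = n_components
        self.max_prevalence = max_prevalence
        self.exclude_substring = exclude_substring

    def fit(self, annotations: dict, genes) -> "GoFeaturizer":
        genes = list(genes)
        n = len(genes)
        if n < 2:
            raise ValueError("need at least 2 genes to fit GO features")
        df_count: dict[str, int] = {}
        names: dict[str, str] = {}
        for g in genes:
            for term_id, term_name in annotations.get(g, ()):
                df_count[term_id] = df_count.get(term_id, 0) + 1
                names[term_id] = term_name
        bad = self.exclude_substring.lower()
        vocab = sorted(
            t for t, c in df_count.items()
            if c < self.max_prevalence * n
            and bad not in names[t].lower()
            and bad not in t.lower()
        )
        self.vocabulary_ = {t: i for i, t in enumerate(vocab)}
        self.term_names_ = {t: names[t] for t in vocab}
        if not vocab:
            self.tfidf_ = None
            self.pca_ = None
            return self
        counts = self._count_matrix(annotations, genes)
        self.tfidf_ = TfidfTransformer(smooth_idf=True, norm="l2")
        weighted = self.tfidf_.fit_transform(counts)
        k = min(self.n_components, len(vocab), len(genes))
        self.pca_ = PCA(n_components=k, svd_solver="full")
        self.pca_.fit(weighted.toarray())
        return self

    def _count_matrix(self, annotations: dict, genes) -> np.ndarray:
        m = np.zeros((len(genes), len(self.vocabulary_)))
        for i, g in enumerate(genes):
            for term_id, _ in annotations.get(g, ()):
                j = self.vocabulary_.get(term_id)
                if j is not None:
                    m[i, j] = 1.0
        return m

    def transform(self, annotations: dict, genes) -> pd.DataFrame:
        genes = list(genes)
        cols = [f"GO{i + 1}" for i in range(self.n_components)]
        if not self.vocabulary_ or self.pca_ is None:
            import warnings

            warnings.warn("no GO terms survived filtering; GO features are all zero")
            return pd.DataFrame(0.0, index=genes, columns=cols)
        weighted = self.tfidf_.transform(self._count_matrix(annotations, genes))
        proj = self.pca_.transform(weighted.toarray())
        out = pd.DataFrame(0.0, index=genes, columns=cols)
        out.iloc[:, : proj.shape[1]] = proj
        return out

    def fit_transform(self, annotations: dict, genes) -> pd.DataFrame:
        return self.fit(annotations, genes).transform(annotations, genes)


def composite_lfc(table: pd.DataFrame, meta: dict[str, DatasetMeta]) -> pd.DataFrame:
    """Per (tissue, species) composite log-fold-change columns.

    Within each group, entries whose paired FDR is >= 0.05 (or missing)
    are set to 0, then the per-gene mean over the group's datasets is
    taken. Column order within a group does not affect the result.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for col, m in meta.items():
        if m.measure.upper() != "LFC":
            continue
        if col not in table.columns:
            raise KeyError(f"LFC column {col!r} declared in metadata but absent from table")
        if not m.fdr_column:
            raise ValueError(f"LFC column {col!r} has no paired FDR column in its metadata")
        if m.fdr_column not in table.columns:
            raise ValueError(f"FDR partner {m.fdr_column!r} of {col!r} absent from table")
        groups.setdefault((m.tissue, m.species), []).append(col)

    out = pd.DataFrame(index=table.index)
    for (tissue, species), cols in sorted(groups.items()):
        vals = []
        for col in sorted(cols):
            lfc = pd.to_numeric(table[col], errors="coerce")
            fdr = pd.to_numeric(table[meta[col].fdr_column], errors="coerce")
            sig = fdr < 0.05  # missing FDR counts as non-significant
            vals.append(lfc.where(sig, 0.0).fillna(0.0))
        out[f"composite_lfc_{tissue}_{species}"] = pd.concat(vals, axis=1).mean(axis=1)
    return out


def correlation_filter(X: pd.DataFrame, threshold: float = 0.75):
    """Drop the lower-variance member of each highly correlated pair.

    Iterates until no pair has |Pearson r| >= threshold; ties on
    variance drop the later column. Returns ``(filtered, dropped)``.
    """
    if X.shape[1] < 2:
        return X.copy(), []
    keep = list(X.columns)
    dropped: list[str] = []
    while True:
        sub = X[keep]
        corr = sub.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < threshold:
            break
        a, b = keep[min(i, j)], keep[max(i, j)]
        va, vb = X[a].var(), X[b].var()
        victim = b if vb <= va else a
        dropped.append(victim)
        keep.remove(victim)
        if len(keep) < 2:
            break
    return X[keep].copy(), dropped


class SymmetricMinMaxScaler:
    """Affine map of each feature onto [-1, 1], fitted on chosen rows.

    Constant features map to 0. Rows outside the fitted range transform
    outside [-1, 1] by design (the transform is fitted on training rows
    and applied unchanged to validation rows).
    """

    def fit(self, X: pd.DataFrame) -> "SymmetricMinMaxScaler":
        if X.shape[0] == 0:
            raise ValueError("cannot fit scaler on zero rows")
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        self.center_ = (hi + lo) / 2.0
        self.halfrange_ = (hi - lo) / 2.0
        self.columns_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        hr = self.halfrange_.replace(0.0, np.nan)
        out = (X[self.columns_] - self.center_) / hr
        return out.fillna(0.0)

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


def split_stratified(y: pd.Series, train_fraction: float = 0.7, seed: int = 0):
    """Label-stratified 70/30 split; returns (train_genes, val_genes)."""
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present to stratify")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    train, val = train_test_split(
        y.index.to_numpy(),
        train_size=train_fraction,
        stratify=y.to_numpy(),
        random_state=seed,
        shuffle=True,
    )
    return pd.Index(train), pd.Index(val)


def assemble_features(
    table: pd.DataFrame,
    meta: dict[str, DatasetMeta],
    topology: pd.DataFrame,
    labels: pd.Series,
    go_features: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Concatenate all engineered blocks into one unscaled matrix.

    Blocks: ordinal-coded categoricals, GC content, conservation score,
    GO PCA components (if supplied), composite LFCs, TPM columns, the
    11 topology features plus a ``topology_missing`` flag for genes
    absent from the graph. Missing numeric values impute to 0.
    """
    genes = table.index.intersection(labels.index)
    if genes.empty:
        raise ValueError("no genes shared between feature table and labels")
    table = table.loc[genes]

    blocks = []
    codes, decode = encode_categoricals(table)
    if not codes.empty:
        blocks.append(codes)
    for col in ("gc_content", "conservation_score"):
        if col in table.columns:
            blocks.append(pd.to_numeric(table[col], errors="coerce").to_frame(col))
    if go_features is not None:
        blocks.append(go_features.reindex(genes))
    blocks.append(composite_lfc(table, meta))
    tpm_cols = sorted(c for c, m in meta.items() if m.measure.upper() == "TPM")
    if tpm_cols:
        blocks.append(table[tpm_cols].apply(pd.to_numeric, errors="coerce"))

    topo = topology.reindex(genes)
    missing_flag = topo.isna().all(axis=1).astype(float).rename("topology_missing")
    topo = topo.fillna(0.0)
    blocks.extend([topo, missing_flag.to_frame()])

    X = pd.concat(blocks, axis=1).astype(float).fillna(0.0)
    prov = {
        "categorical_decode": decode,
        "n_genes": int(len(genes)),
        "dropped_features": [],
    }
    return FeatureMatrix(X, labels.loc[genes].astype(int), prov)


# -- readers / writers -------------------------------------------------------

def read_feature_table(path: str | Path, sidecar: str | Path):
    """Read the raw gene table (TSV) and its YAML omics-column sidecar.

    The sidecar maps column name -> {tissue, species, modality, measure,
    fdr_column (LFC only)}.
    """
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    with open(sidecar) as fh:
        raw = yaml.safe_load(fh) or {}
    meta = {
        col: DatasetMeta(
            tissue=str(spec["tissue"]),
            species=str(spec["species"]),
            modality=str(spec.get("modality", "transcriptome")),
            measure=str(spec["measure"]),
            fdr_column=spec.get("fdr_column"),
        )
        for col, spec in raw.items()
    }
    return table, meta


def read_go_annotations(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Two-column TSV ``gene_id <tab> term_id|term_name``, one pair per line."""
    out: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")
            term_id, _, term_name = term.partition("|")
            out.setdefault(gene, []).append((term_id, term_name))
    return out


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    df = fm.X.copy()
    df["label"] = fm.y
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    y = df.pop("label").astype(int)
    return FeatureMatrix(df, y)
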
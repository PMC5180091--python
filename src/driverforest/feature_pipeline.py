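"""Feature preparation for the driver-gene classifier.

Covers the derived features that require computation (genomic density,
protein-interaction counts, betweenness centrality, tissue-expression
summaries, length-normalized PTM counts) and the three-stage cleaning
procedure applied before training: sparse-feature removal, correlated-feature
removal, then k-nearest-neighbor imputation.  The stage order is fixed —
filters only ever drop columns and never alter cell values, and imputation
leaves observed cells bit-identical.

A ``FeatureTable`` is a genes × features DataFrame plus a declared type per
column (continuous / binary / categorical); missing cells are NaN (written as
empty fields on disk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics.pairwise import nan_euclidean_distances

__all__ = [
    "FeatureTable",
    "FilterConfig",
    "genomic_density",
    "ppi_count",
    "betweenness",
    "tissue_summary",
    "normalize_ptm",
    "remove_sparse",
    "remove_correlated",
    "impute_knn",
    "encode_features",
    "prepare_features",
]

FEATURE_TYPES = ("continuous", "binary", "categorical")


@dataclass
class FeatureTable:
    """Genes × named features with per-column type metadata.

    ``data`` is indexed by gene_id; ``types`` maps every column to one of
    ``continuous``, ``binary`` or ``categorical``; ``categories`` optionally
    tags columns with a provenance group (e.g. ``tumor_genomics``) used by
    feature-set contrast experiments.
    """

    data: pd.DataFrame
    types: dict[str, str]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.types) != set(self.data.columns):
            raise ValueError("types must cover exactly the data columns")
        bad = {c: t for c, t in self.types.items() if t not in FEATURE_TYPES}
        if bad:
            raise ValueError(f"unknown feature types: {bad}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids")

    def columns_of_type(self, kind: str) -> list[str]:
        return [c for c in self.data.columns if self.types[c] == kind]

    def subset(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(
            data=self.data[columns].copy(),
            types={c: self.types[c] for c in columns},
            categories={c: g for c, g in self.categories.items() if c in columns},
        )

    def write_tsv(self, path: str | Path) -> None:
        """Write values to ``path`` and types/categories to ``<path>.types.tsv``."""
        path = Path(path)
        self.data.to_csv(path, sep="\t", na_rep="", index_label="gene_id")
        meta = pd.DataFrame(
            {
                "type": pd.Series(self.types),
                "category": pd.Series(self.categories).reindex(self.data.columns),
            }
        )
        meta.to_csv(path.with_suffix(path.suffix + ".types.tsv"), sep="\t",
                    index_label="feature")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        data = pd.read_csv(path, sep="\t", index_col="gene_id")
        meta = pd.read_csv(
            path.with_suffix(path.suffix + ".types.tsv"), sep="\t", index_col="feature"
        )
        categories = meta["category"].dropna().to_dict()
        return cls(data=data, types=meta["type"].to_dict(), categories=categories)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the cleaning stages.

    ``freq_ratio_threshold`` and ``unique_pct_threshold`` define sparse
    features (both criteria must hold for removal); ``corr_threshold`` bounds
    allowed pairwise |Spearman|; ``knn_k`` neighbors are averaged during
    imputation.
    """

    freq_ratio_threshold: float = 97.0 / 3.0
    unique_pct_threshold: float = 3.0
    corr_threshold: float = 0.95
    knn_k: int = 5

    def __post_init__(self) -> None:
        if self.freq_ratio_threshold <= 0 or self.unique_pct_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in (0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


# ---------------------------------------------------------------------------
# derived features


def genomic_density(coords: pd.DataFrame, window_bp: float = 4e6) -> pd.Series:
    """Local gene density, normalized to mean 1.

    For each gene, count genes on the same chromosome (including the gene
    itself) whose center position lies within ``window_bp`` up- or downstream
    of the gene's center, then divide by the mean count over all genes.
    ``coords`` needs columns ``chrom`` and ``center_bp``; genes with a missing
    center get a missing density.
    """
    out = pd.Series(np.nan, index=coords.index, name="genomic_density")
    valid = coords["center_bp"].notna()
    counts = pd.Series(np.nan, index=coords.index)
    for _, sub in coords[valid].groupby("chrom"):
        centers = sub["center_bp"].to_numpy(dtype=float)
        order = np.sort(centers)
        lo = np.searchsorted(order, centers - window_bp, side="left")
        hi = np.searchsorted(order, centers + window_bp, side="right")
        counts.loc[sub.index] = hi - lo
    mean = counts.mean()
    if mean and mean > 0:
        out[valid] = counts[valid] / mean
    return out


def ppi_count(counts_a: pd.Series, counts_b: pd.Series) -> pd.Series:
    """Average interaction count over two interaction databases.

    The mean of the available values: genes covered by only one source use
    that source alone; genes missing in both stay missing.
    """
    both = pd.concat([counts_a, counts_b], axis=1)
    if (both < 0).any().any():
        raise ValueError("interaction counts must be non-negative")
    return both.mean(axis=1, skipna=True).rename("n_ppi")


def betweenness(edges: pd.DataFrame | list[tuple[str, str]]) -> pd.Series:
    """Unnormalized shortest-path betweenness centrality (Brandes).

    Accepts a two-column edge list; self-loops are dropped with a warning.
    Genes absent from the graph are simply absent from the result (callers
    reindex and fill 0).
    """
    if isinstance(edges, pd.DataFrame):
        pairs = list(edges.itertuples(index=False, name=None))
    else:
        pairs = list(edges)
    loops = [(u, v) for u, v in pairs if u == v]
    if loops:
        warnings.warn(f"dropping {len(loops)} self-loops", stacklevel=2)
    g = nx.Graph((u, v) for u, v in pairs if u != v)
    bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(bc, name="betweenness").sort_index()


def tissue_summary(expression: pd.DataFrame) -> pd.DataFrame:
    """Median expression and across-tissue variation per gene.

    The variation statistic follows the convention of the source feature
    table: mean divided by sample standard deviation (the reciprocal of the
    usual coefficient of variation); set ``attrs['cv_convention']`` on the
    result for provenance.  Genes with fewer than two observed tissues, or a
    zero standard deviation, get a missing variation.
    """
    median = expression.median(axis=1, skipna=True)
    n_obs = expression.notna().sum(axis=1)
    mean = expression.mean(axis=1, skipna=True)
    sd = expression.std(axis=1, ddof=1, skipna=True)
    variation = mean / sd.where(sd > 0)
    variation[n_obs < 2] = np.nan
    median[n_obs == 0] = np.nan
    out = pd.DataFrame(
        {"expression_median": median, "expression_variation": variation}
    )
    out.attrs["cv_convention"] = "mean_over_sd"
    return out


def normalize_ptm(site_counts: pd.DataFrame, cds_length_aa: pd.Series) -> pd.DataFrame:
    """Per-PTM-type site counts divided by protein length in amino acids.

    Genes with a missing CDS length get missing values in every PTM column.
    """
    lengths = pd.Series(cds_length_aa, dtype=float).reindex(site_counts.index)
    if (lengths.dropna() <= 0).any():
        raise ValueError("CDS lengths must be positive")
    return site_counts.div(lengths, axis=0).add_prefix("ptm_rate_")


# ---------------------------------------------------------------------------
# cleaning stages


def _value_counts_with_missing(col: pd.Series) -> pd.Series:
    """Value frequencies where a missing cell counts as its own value."""
    return col.astype(object).where(col.notna(), "__missing__").value_counts()


def remove_sparse(
    table: FeatureTable, config: FilterConfig | None = None
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop near-constant, low-cardinality features.

    A feature is removed iff BOTH hold: the frequency ratio of its most
    common to second most common value exceeds ``freq_ratio_threshold``
    (infinite for single-valued columns), AND its number of distinct values is
    under ``unique_pct_threshold`` percent of the gene count.  A missing
    marker counts as a value on both criteria.
    """
    config = config or FilterConfig()
    n = len(table.data)
    records = []
    removed = []
    for col in table.data.columns:
        counts = _value_counts_with_missing(table.data[col])
        if len(counts) == 1:
            ratio = np.inf
        else:
            ratio = counts.iloc[0] / counts.iloc[1]
        unique_pct = 100.0 * len(counts) / n
        drop = ratio > config.freq_ratio_threshold and (
            unique_pct < config.unique_pct_threshold
        )
        if drop:
            removed.append(col)
            records.append(
                {"feature": col, "reason": "sparse",
                 "freq_ratio": ratio, "unique_pct": unique_pct}
            )
    kept = [c for c in table.data.columns if c not in set(removed)]
    return table.subset(kept), pd.DataFrame(
        records, columns=["feature", "reason", "freq_ratio", "unique_pct"]
    )


def _spearman_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations, average ranks for ties.

    Constant columns have undefined correlations, treated as 0 with a warning.
    """
    corr = df.corr(method="spearman", min_periods=2)
    if corr.isna().any().any():
        warnings.warn(
            "undefined correlations (constant or disjoint columns) treated as 0",
            stacklevel=3,
        )
        corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _encode_for_corr(table: FeatureTable) -> pd.DataFrame:
    """Numeric view for correlation screening; categoricals become rank codes."""
    out = {}
    for col in table.data.columns:
        s = table.data[col]
        if table.types[col] == "categorical":
            codes = s.astype("category").cat.codes.astype(float)
            codes[s.isna()] = np.nan
            out[col] = codes
        else:
            out[col] = pd.to_numeric(s, errors="coerce")
    return pd.DataFrame(out, index=table.data.index)


def remove_correlated(
    table: FeatureTable, config: FilterConfig | None = None
) -> tuple[FeatureTable, pd.DataFrame]:
    """Greedy elimination of highly inter-correlated features.

    Repeatedly locate the pair with the largest |Spearman| above
    ``corr_threshold`` and drop whichever member has the greater mean absolute
    correlation with all remaining features, recomputing until no pair
    exceeds the threshold.  Ties in |rho| resolve to the lexicographically
    first pair; exactly one member of an exact-duplicate pair survives.
    """
    config = config or FilterConfig()
    numeric = _encode_for_corr(table)
    corr = _spearman_matrix(numeric).abs()
    kept = list(corr.columns)
    records = []
    while len(kept) > 1:
        sub = corr.loc[kept, kept].copy()
        np.fill_diagonal(sub.values, 0.0)
        best = sub.stack().sort_index()
        top = best.max()
        if top <= config.corr_threshold:
            break
        pairs = sorted(
            (min(a, b), max(a, b)) for (a, b) in best.index[best == top]
        )
        a, b = pairs[0]
        mean_a = sub.loc[a, [c for c in kept if c != a]].mean()
        mean_b = sub.loc[b, [c for c in kept if c != b]].mean()
        drop = a if (mean_a > mean_b or (mean_a == mean_b and a < b)) else b
        keep = b if drop == a else a
        records.append(
            {"feature": drop, "reason": "correlated",
             "abs_spearman": top, "partner": keep}
        )
        kept.remove(drop)
    kept_order = [c for c in table.data.columns if c in set(kept)]
    return table.subset(kept_order), pd.DataFrame(
        records, columns=["feature", "reason", "abs_spearman", "partner"]
    )


def impute_knn(
    table: FeatureTable, config: FilterConfig | None = None
) -> FeatureTable:
    """Fill missing cells from the k nearest genes in feature space.

    Distances are Euclidean over columns standardized to zero mean and unit
    variance, restricted to mutually observed coordinates and rescaled by the
    number of coordinates used (so partial overlap does not shrink
    distances).  Each missing cell becomes the mean of the feature over the
    ``knn_k`` nearest genes that observe it; when none of those neighbors
    observe the feature, the column median over all genes is used instead.
    Observed cells are untouched; categorical columns fall back to the
    nearest observing neighbor's value (modal among neighbors).
    """
    config = config or FilterConfig()
    k = config.knn_k
    if len(table.data) < k + 1:
        raise ValueError(f"need at least {k + 1} genes for {k}-NN imputation")
    all_missing = table.data.columns[table.data.isna().all()]
    if len(all_missing):
        raise ValueError(
            f"features missing in every gene (remove upstream): {list(all_missing)}"
        )
    numeric = _encode_for_corr(table)
    mu = numeric.mean()
    sd = numeric.std(ddof=0).replace(0.0, 1.0)
    z = ((numeric - mu) / sd).to_numpy(dtype=float)
    # nan_euclidean scales squared distances by n_total/n_observed already
    dist = nan_euclidean_distances(z, z)
    np.fill_diagonal(dist, np.inf)
    dist[np.isnan(dist)] = np.inf  # gene pairs with no shared observed feature

    data = table.data.copy()
    medians = numeric.median()
    gene_pos = {g: i for i, g in enumerate(data.index)}
    for col in data.columns:
        missing_genes = data.index[data[col].isna()]
        if not len(missing_genes):
            continue
        col_obs = data[col].notna()
        is_cat = table.types[col] == "categorical"
        for g in missing_genes:
            i = gene_pos[g]
            order = np.argsort(dist[i], kind="stable")
            neighbors = [data.index[j] for j in order[:k] if np.isfinite(dist[i][j])]
            observed = [nb for nb in neighbors if col_obs.loc[nb]]
            if not observed:
                if is_cat:
                    data.loc[g, col] = data.loc[col_obs, col].mode().iloc[0]
                else:
                    data.loc[g, col] = medians[col]
            elif is_cat:
                data.loc[g, col] = data.loc[observed, col].mode().iloc[0]
            else:
                value = data.loc[observed, col].astype(float).mean()
                if table.types[col] == "binary":
                    value = float(round(value))
                data.loc[g, col] = value
    return FeatureTable(data=data, types=dict(table.types),
                        categories=dict(table.categories))


def encode_features(table: FeatureTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete table → numeric matrix plus an invertible column map.

    Binary columns pass through as 0/1, continuous pass through, categorical
    columns expand to one indicator per declared level.  Returns the matrix
    and a column map DataFrame (encoded column → source feature, level).
    """
    if table.data.isna().any().any():
        raise ValueError("encode_features requires a complete table")
    blocks = []
    map_rows = []
    for col in table.data.columns:
        kind = table.types[col]
        if kind == "categorical":
            s = table.data[col].astype("category")
            levels = list(s.cat.categories)
            onehot = pd.get_dummies(s)
            onehot.columns = [f"{col}={lvl}" for lvl in levels]
            blocks.append(onehot.astype(float))
            for lvl in levels:
                map_rows.append(
                    {"column": f"{col}={lvl}", "feature": col, "level": lvl}
                )
        else:
            values = pd.to_numeric(table.data[col])
            if kind == "binary" and not set(values.unique()) <= {0, 1, 0.0, 1.0}:
                raise ValueError(f"binary column {col!r} has non-0/1 values")
            blocks.append(values.astype(float).to_frame(col))
            map_rows.append({"column": col, "feature": col, "level": None})
    matrix = pd.concat(blocks, axis=1)
    return matrix, pd.DataFrame(map_rows).set_index("column")


def decode_columns(column_map: pd.DataFrame, columns: list[str]) -> list[str]:
    """Invert encoded column names back to source feature names (deduplicated)."""
    feats = column_map.loc[columns, "feature"]
    return list(dict.fromkeys(feats))


def prepare_features(
    table: FeatureTable, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the fixed cleaning order: sparse → correlated → impute → encode.

    Returns (encoded matrix, column map, removed-feature report).
    """
    config = config or FilterConfig()
    t1, rep1 = remove_sparse(table, config)
    t2, rep2 = remove_correlated(t1, config)
    t3 = impute_knn(t2, config)
    matrix, column_map = encode_features(t3)
    report = pd.concat([rep1, rep2], ignore_index=True)
    return matrix, column_map, report


def spearman_abs(x, y) -> float:
    """|Spearman rho| of two vectors over pairwise-complete cells (helper)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    rx, ry = rankdata(x[ok]), rankdata(y[ok])
    if rx.std() == 0 or ry.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(rx, ry)[0, 1]))
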
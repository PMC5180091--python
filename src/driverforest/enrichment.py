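"""Count-based enrichment statistics for gene-set analyses.

The headline analysis this module supports asks whether tumor suppressor
genes (TSGs) are overrepresented among the genes encoding the very largest
proteins in the genome, and in particular among large proteins with a
documented role in chromosome organization.  The building blocks are
deliberately simple and exact: hypergeometric tail probabilities computed in
log space, fold-enrichment ratios, Welch two-sample t statistics, and
protein-size percentiles with max-rank tie handling.

No multiple-testing correction is applied here; callers that run many
contrasts should correct downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import t as t_dist

__all__ = [
    "EnrichmentResult",
    "WelchResult",
    "SizeAnnotationSet",
    "hypergeom_log_pmf",
    "hypergeom_upper_tail",
    "hypergeom_lower_tail",
    "fold_enrichment",
    "welch_t",
    "size_percentiles",
    "top_fraction",
    "intersect_and_profile",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of a category inside a selected gene set.

    ``N`` genes in the population carry ``K`` category members; ``n`` genes
    were selected and ``k`` of them are category members.  ``p_upper`` is
    P(X >= k) and ``fold`` the prevalence ratio inside versus outside the
    selection (infinite when every category member is inside).
    """

    N: int
    K: int
    n: int
    k: int
    p_upper: float
    fold: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"k={self.k} outside [0, min(n={self.n}, K={self.K})]")


@dataclass(frozen=True)
class WelchResult:
    """Welch unequal-variance t-test summary."""

    t: float
    df: float
    p: float


@dataclass
class SizeAnnotationSet:
    """Genes at the top of the protein-size distribution carrying an annotation.

    Holds the size quantile used for the cut, the selected gene list, the
    per-gene CDS lengths and genome percentiles, and a composition report of
    driver labels / predictions inside versus outside the set.
    """

    quantile: float
    genes: list[str]
    cds_lengths: pd.Series
    percentiles: pd.Series
    composition: pd.DataFrame
    enrichment: EnrichmentResult
    subprofiles: pd.DataFrame = field(default_factory=pd.DataFrame)


def _validate_counts(N: int, K: int, n: int) -> None:
    if N < 0 or K < 0 or n < 0 or K > N or n > N:
        raise ValueError(f"invalid hypergeometric counts N={N}, K={K}, n={n}")


def hypergeom_log_pmf(N: int, K: int, n: int, k: int) -> float:
    """log P(X = k) for X ~ Hypergeometric(N, K, n), via log-factorials."""
    _validate_counts(N, K, n)
    if k < max(0, n - (N - K)) or k > min(n, K):
        return -np.inf
    return float(
        gammaln(K + 1)
        - gammaln(k + 1)
        - gammaln(K - k + 1)
        + gammaln(N - K + 1)
        - gammaln(n - k + 1)
        - gammaln(N - K - (n - k) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Inclusive upper tail P(X >= k), exact in log space.

    ``k`` above its support maximum is a vacuous request and returns 0 with a
    warning; ``k <= 0`` returns 1 exactly.
    """
    _validate_counts(N, K, n)
    k_max = min(n, K)
    if k > k_max:
        warnings.warn(
            f"k={k} exceeds min(n, K)={k_max}; upper tail is empty", stacklevel=2
        )
        return 0.0
    if k <= max(0, n - (N - K)):
        return 1.0
    terms = [hypergeom_log_pmf(N, K, n, j) for j in range(k, k_max + 1)]
    return float(np.exp(logsumexp(terms)))


def hypergeom_lower_tail(N: int, K: int, n: int, k: int) -> float:
    """Inclusive lower tail P(X <= k), exact in log space."""
    _validate_counts(N, K, n)
    if k < max(0, n - (N - K)):
        return 0.0
    if k >= min(n, K):
        return 1.0
    terms = [
        hypergeom_log_pmf(N, K, n, j) for j in range(max(0, n - (N - K)), k + 1)
    ]
    return float(np.exp(logsumexp(terms)))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Prevalence of a category inside a selection over its prevalence outside.

    fold = (k/n) / ((K-k)/(N-n)).  Returns ``inf`` when the category is
    entirely inside the selection (K == k) and 0.0 when k == 0.
    """
    if n <= 0 or n >= N:
        raise ValueError("need 0 < n < N")
    if k > K:
        raise ValueError("k cannot exceed K")
    if K == k:
        if k == 0:
            return 0.0
        return float("inf")
    return (k / n) / ((K - k) / (N - n))


def welch_t(sample_x, sample_y) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (x̄ − ȳ) / sqrt(s²ₓ/nₓ + s²ᵧ/nᵧ) with Welch–Satterthwaite degrees
    of freedom; sample variances use n−1.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def size_percentiles(cds_lengths: pd.Series) -> pd.Series:
    """Genome percentile of each gene's protein size, max-rank for ties.

    The largest gene sits at the 100.0th percentile (100 · N/N); tied lengths
    share the percentile of the highest tied rank, mirroring how published
    driver-size tables report "percentile in genome".  Genes with missing
    length are dropped with a warning.
    """
    lengths = pd.Series(cds_lengths, dtype=float)
    missing = lengths.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} genes lack a CDS length and are excluded",
            stacklevel=2,
        )
        lengths = lengths[~missing]
    if (lengths <= 0).any():
        raise ValueError("CDS lengths must be positive")
    ranks = lengths.rank(method="max")
    return 100.0 * ranks / len(lengths)


def top_fraction(cds_lengths: pd.Series, q: float) -> list[str]:
    """Genes in the top ``q`` fraction by protein size.

    The cut value is the ⌈qN⌉-th largest length; every gene at least that
    long is kept, so ties at the boundary are never split and the selection
    holds exactly ⌈qN⌉ genes when lengths are distinct.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    lengths = pd.Series(cds_lengths, dtype=float).dropna()
    k = max(1, int(np.ceil(q * len(lengths))))
    cutoff = lengths.nlargest(k).iloc[-1]
    return sorted(lengths.index[lengths >= cutoff])


def intersect_and_profile(
    cds_lengths: pd.Series,
    annotations: pd.DataFrame,
    labels: pd.Series,
    primary_flag: str,
    q: float = 0.05,
    predicted_tsg: list[str] | None = None,
    subprofile_flags: list[str] | None = None,
    mutually_exclusive: bool = False,
) -> SizeAnnotationSet:
    """Profile the intersection of very large proteins with an annotation.

    Selects the genes in the top ``q`` size fraction that carry the boolean
    ``primary_flag`` annotation (e.g. chromosome organization), then reports
    how many high-confidence TSGs/OGs (from ``labels``, values in
    {"TSG", "OG", ...}) and optionally top predicted TSGs fall inside versus
    outside, with a hypergeometric enrichment of TSGs in the set against the
    full universe.

    ``subprofile_flags`` breaks the selected set down by secondary annotations
    (chromatin modification, histone modification, ...).  With
    ``mutually_exclusive`` each gene counts only toward the first flag it
    carries, in the given order; otherwise categories may overlap.
    """
    if primary_flag not in annotations.columns:
        raise KeyError(f"annotation column {primary_flag!r} absent")
    universe = cds_lengths.dropna().index
    top = top_fraction(cds_lengths, q)
    flagged = annotations.index[annotations[primary_flag].astype(bool)]
    selected = sorted(set(top) & set(flagged))
    pct = size_percentiles(cds_lengths)

    N = len(universe)
    n = len(selected)
    tsg_all = [g for g in universe if labels.get(g) == "TSG"]
    og_all = [g for g in universe if labels.get(g) == "OG"]
    inside = set(selected)
    rows = {
        "TSG": (len(set(tsg_all) & inside), len(tsg_all)),
        "OG": (len(set(og_all) & inside), len(og_all)),
    }
    if predicted_tsg is not None:
        pred = [g for g in predicted_tsg if g in set(universe)]
        rows["predicted_TSG"] = (len(set(pred) & inside), len(pred))
    composition = pd.DataFrame(
        {
            "inside": {cls: v[0] for cls, v in rows.items()},
            "total": {cls: v[1] for cls, v in rows.items()},
        }
    )
    composition["share"] = composition["inside"] / composition["total"].where(
        composition["total"] > 0
    )

    K = len(tsg_all)
    k = int(composition.loc["TSG", "inside"]) if K else 0
    if n == 0:
        enrich = EnrichmentResult(N=N, K=K, n=0, k=0, p_upper=1.0, fold=0.0)
    else:
        enrich = EnrichmentResult(
            N=N,
            K=K,
            n=n,
            k=k,
            p_upper=hypergeom_upper_tail(N, K, n, k),
            fold=fold_enrichment(k, n, K, N) if 0 < n < N else 0.0,
        )

    sub = pd.DataFrame()
    if subprofile_flags:
        missing_cols = [c for c in subprofile_flags if c not in annotations.columns]
        if missing_cols:
            raise KeyError(f"annotation columns absent: {missing_cols}")
        counts: dict[str, int] = {c: 0 for c in subprofile_flags}
        for g in selected:
            for c in subprofile_flags:
                if bool(annotations.loc[g, c]):
                    counts[c] += 1
                    if mutually_exclusive:
                        break
        sub = pd.DataFrame(
            {
                "count": pd.Series(counts),
                "share": pd.Series(counts) / n if n else np.nan,
            }
        )

    return SizeAnnotationSet(
        quantile=q,
        genes=selected,
        cds_lengths=cds_lengths.loc[selected],
        percentiles=pct.reindex(selected),
        composition=composition,
        enrichment=enrich,
        subprofiles=sub,
    )
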
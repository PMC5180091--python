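"""Evaluation protocol for ranked driver-gene predictions.

Rankings are scored as retrieval problems: precision at N for each
confidence tier, with panel-exclusion semantics (the high-confidence panel
excludes nothing; the medium panel excludes high; the low panel excludes
high and medium), cumulative detection counts, the out-of-bag ROC separating
TSGs from OGs within the positives, and a training-set-perturbation
stability check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .pu_forest import (
    ForestConfig,
    PosteriorTable,
    fit_forest,
    oob_posteriors,
    rank_genes,
)

__all__ = [
    "PrecisionCurve",
    "precision_at_n",
    "cumulative_detection",
    "tsg_og_auc",
    "stability",
    "feature_set_contrast",
]

TIER_EXCLUSIONS = {
    "high": [],
    "medium": ["high_TSG", "high_OG"],
    "low": ["high_TSG", "high_OG", "medium"],
}


@dataclass
class PrecisionCurve:
    """Precision (or hit counts) of a target tier along a filtered ranking."""

    tier: str
    n_grid: np.ndarray
    precision: np.ndarray
    hits: np.ndarray
    excluded_tiers: list[str]


def _filtered_ranking(
    ranking: list[str], labels, exclude_tiers: list[str]
) -> list[str]:
    tiers = labels.tiers if hasattr(labels, "tiers") else labels
    excluded = set(tiers.index[tiers.isin(exclude_tiers)])
    return [g for g in ranking if g not in excluded]


def _tier_genes(labels, tier: str) -> set[str]:
    tiers = labels.tiers if hasattr(labels, "tiers") else labels
    if tier == "high":
        wanted = ["high_TSG", "high_OG"]
    else:
        wanted = [tier]
    return set(tiers.index[tiers.isin(wanted)])


def precision_at_n(
    ranking: list[str],
    labels,
    tier: str,
    exclude_tiers: list[str] | None = None,
    n_max: int = 200,
) -> PrecisionCurve:
    """Fraction of the top-N filtered ranking belonging to the target tier.

    Genes in ``exclude_tiers`` are removed from the ranked list before
    counting, so successive panels (high → medium → low) do not re-count the
    genes a previous panel already considered.  With the tier's own genes as
    the only relevant items, precision at N equals the detected fraction of
    the tier within the top N.
    """
    if exclude_tiers is None:
        exclude_tiers = TIER_EXCLUSIONS.get(tier, [])
    filtered = _filtered_ranking(ranking, labels, exclude_tiers)
    if n_max > len(filtered):
        warnings.warn(
            f"n_max={n_max} exceeds filtered list length {len(filtered)}; truncating",
            stacklevel=2,
        )
        n_max = len(filtered)
    targets = _tier_genes(labels, tier)
    is_hit = np.array([g in targets for g in filtered[:n_max]], dtype=int)
    hits = np.cumsum(is_hit)
    grid = np.arange(1, n_max + 1)
    return PrecisionCurve(
        tier=tier,
        n_grid=grid,
        precision=hits / grid,
        hits=hits,
        excluded_tiers=list(exclude_tiers),
    )


def cumulative_detection(
    ranking: list[str],
    labels,
    tier: str,
    exclude_tiers: list[str] | None = None,
    n_max: int | None = None,
) -> PrecisionCurve:
    """Unnormalized non-decreasing count of tier genes among the top N."""
    if exclude_tiers is None:
        exclude_tiers = TIER_EXCLUSIONS.get(tier, [])
    filtered = _filtered_ranking(ranking, labels, exclude_tiers)
    if n_max is None:
        n_max = len(filtered)
    curve = precision_at_n(ranking, labels, tier, exclude_tiers, n_max)
    return curve


def tsg_og_auc(posteriors: PosteriorTable, high_labels: pd.Series) -> float:
    """OOB ROC AUC for separating TSGs (label 1) from OGs (label 0).

    The score is the conditional posterior of TSG given driver,
    P_TSG / (P_TSG + P_OG); positives with a zero denominator are dropped
    with a warning.  AUC via the Mann–Whitney rank statistic with midranks
    for ties.
    """
    t = posteriors.table.loc[high_labels.index]
    denom = t["P_TSG"] + t["P_OG"]
    bad = denom <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} positives have P_TSG + P_OG = 0; dropped",
            stacklevel=2,
        )
    score = (t["P_TSG"] / denom)[~bad]
    y = (high_labels[~bad] == "TSG").to_numpy()
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both TSG and OG examples")
    ranks = rankdata(score.to_numpy())
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return float(auc)


def stability(
    X: pd.DataFrame,
    training_labels: pd.Series,
    forest_config: ForestConfig,
    n_replicates: int = 10,
    drop_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank agreement across retrainings with perturbed positive sets.

    Each replicate removes ``drop_fraction`` of the positives (at least one
    of each role must survive), refits the forest, and driver rankings over
    non-training genes are compared pairwise by Spearman correlation.
    Returns the pairwise correlation table (long format).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    positives = training_labels.index[training_labels.isin(["TSG", "OG"])]
    non_training = X.index.difference(training_labels.index)
    scores = {}
    for r in range(n_replicates):
        drop_n = int(round(drop_fraction * len(positives)))
        dropped = (
            set(rng.choice(positives, size=drop_n, replace=False))
            if drop_n
            else set()
        )
        kept = training_labels.drop(index=list(dropped))
        for role in ("TSG", "OG"):
            if not (kept == role).any():
                raise ValueError(f"replicate {r} dropped every {role}")
        # forest seed fixed across replicates: only the training-set
        # perturbation varies, so drop_fraction 0 reproduces exactly
        model = fit_forest(X, kept, forest_config)
        post = oob_posteriors(model, X)
        scores[r] = post.table.loc[non_training, "driver_score"]
    rows = []
    for a in range(n_replicates):
        for b in range(a + 1, n_replicates):
            rho = spearmanr(scores[a], scores[b]).statistic
            rows.append({"rep_a": a, "rep_b": b, "spearman": float(rho)})
    return pd.DataFrame(rows)


def feature_set_contrast(
    X: pd.DataFrame,
    column_map: pd.DataFrame,
    feature_categories: dict[str, str],
    training_labels: pd.Series,
    labels,
    forest_config: ForestConfig,
    tiers: tuple[str, ...] = ("high", "medium", "low"),
    n_max: int = 200,
    tumor_tag: str = "tumor_genomics",
) -> dict[str, dict[str, PrecisionCurve]]:
    """Precision-at-N under three feature configurations.

    Fits the forest on (a) all features, (b) all except the columns whose
    source feature carries ``tumor_tag``, and (c) only those columns, and
    returns one PrecisionCurve per tier per configuration on a shared N
    grid.  Only structural comparisons are asserted by callers — which
    configuration wins is a property of the data.
    """
    tagged_features = {f for f, c in feature_categories.items() if c == tumor_tag}
    tumor_cols = [
        c for c in X.columns if column_map.loc[c, "feature"] in tagged_features
    ]
    non_tumor_cols = [c for c in X.columns if c not in set(tumor_cols)]
    variants = {
        "all": list(X.columns),
        "non_tumor": non_tumor_cols,
        "tumor_only": tumor_cols,
    }
    out: dict[str, dict[str, PrecisionCurve]] = {}
    for name, cols in variants.items():
        if not cols:
            raise ValueError(f"feature variant {name!r} has no columns")
        model = fit_forest(X[cols], training_labels, forest_config)
        post = oob_posteriors(model, X[cols])
        ranking = rank_genes(post, mode="driver")
        out[name] = {
            tier: precision_at_n(ranking, labels, tier, n_max=n_max)
            for tier in tiers
        }
    return out
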
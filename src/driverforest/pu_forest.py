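"""Positive-unlabeled random forest with exact out-of-bag bookkeeping.

The training data holds a small positive class (high-confidence TSGs and
OGs) against a ~97-fold larger pool of background genes that certainly
contains unrecognized drivers — a positive-unlabeled setting.  Each tree in
the ensemble is therefore grown on a *stratified* bootstrap: the full
positive count drawn with replacement from the positives (keeping their
TSG/OG labels) plus an equally sized draw from the background stratum.  The
down-sampling equalizes the strata per tree while the ensemble still sees the
whole background pool.

Every tree records its exact in-bag gene multiset.  A gene's posterior
(P_TSG, P_OG, P_BG) averages the leaf class proportions of precisely the
trees whose bag excluded it — out-of-bag estimation — so training genes are
scored without self-influence, and genes outside the training tiers are
scored by every tree.  Because of the per-tree down-sampling these scores are
ranking statistics, not calibrated probabilities.

Tree growth itself (CART, Gini impurity, ``mtry`` features per split) is
delegated to :class:`sklearn.tree.DecisionTreeClassifier`; the ensemble
logic, bag bookkeeping, OOB aggregation and unnormalized Gini importance
live here.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ForestConfig",
    "TreeRecord",
    "ForestModel",
    "PosteriorTable",
    "sample_training_set",
    "fit_tree",
    "fit_forest",
    "oob_posteriors",
    "rank_genes",
    "feature_importance",
    "gini_impurity",
    "gini_decrease",
]

CLASSES = ("TSG", "OG", "BG")


@dataclass(frozen=True)
class ForestConfig:
    """Ensemble hyperparameters.

    ``n_trees`` defaults to a desk-scale 2,000 (the full-scale analysis used
    100,000); ``mtry`` defaults to ⌊√p⌋ at fit time; trees grow to purity
    (``min_node_size`` 1, no depth cap).  ``positive_draw`` / ``bg_draw``
    default to the positive count, giving the balanced per-tree bag.
    ``replace_positives`` switches the positive draw to without-replacement
    sampling of the full stratum if desired.
    """

    n_trees: int = 2000
    mtry: int | None = None
    min_node_size: int = 1
    max_depth: int | None = None
    seed: int = 0
    positive_draw: int | None = None
    bg_draw: int | None = None
    replace_positives: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")


@dataclass
class TreeRecord:
    """One fitted tree plus its exact in-bag gene multiset."""

    tree: DecisionTreeClassifier
    in_bag_genes: np.ndarray  # gene positions (with multiplicity)
    class_order: np.ndarray   # tree.classes_ mapped to CLASSES indices


@dataclass
class ForestModel:
    """Fitted PU ensemble over a fixed gene universe and feature matrix."""

    trees: list[TreeRecord]
    config: ForestConfig
    gene_index: pd.Index
    feature_names: list[str]
    version: int = 1

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError("not a ForestModel file")
        return model


@dataclass
class PosteriorTable:
    """Per-gene OOB class posteriors, driver score and rank."""

    table: pd.DataFrame  # columns P_TSG, P_OG, P_BG, n_oob_trees, driver_score, rank

    def defined(self) -> pd.DataFrame:
        return self.table[self.table["n_oob_trees"] > 0]


def _tree_seed(master_seed: int, tree_index: int) -> np.random.SeedSequence:
    """Counter-based per-tree seed: reproducible independently of order."""
    return np.random.SeedSequence(entropy=int(master_seed),
                                  spawn_key=(int(tree_index),))


def sample_training_set(
    labels: pd.Series, config: ForestConfig, tree_seed
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified bootstrap for one tree.

    ``labels`` maps gene_id → class in {TSG, OG, BG}.  Draws
    ``positive_draw`` genes with replacement from the positive stratum
    (TSG ∪ OG, keeping their labels) and ``bg_draw`` with replacement from
    the background stratum.  Returns (gene positions into ``labels.index``,
    class labels), deterministic given ``tree_seed``.
    """
    rng = np.random.default_rng(tree_seed)
    y = labels.to_numpy()
    pos_idx = np.flatnonzero((y == "TSG") | (y == "OG"))
    bg_idx = np.flatnonzero(y == "BG")
    if len(pos_idx) == 0 or len(bg_idx) == 0:
        raise ValueError("both the positive and background strata must be nonempty")
    n_pos = config.positive_draw or len(pos_idx)
    n_bg = config.bg_draw or n_pos
    if config.replace_positives:
        pos_draw = rng.choice(pos_idx, size=n_pos, replace=True)
    else:
        pos_draw = rng.choice(pos_idx, size=min(n_pos, len(pos_idx)),
                              replace=False)
    bg_draw = rng.choice(bg_idx, size=n_bg, replace=True)
    bag = np.concatenate([pos_draw, bg_draw])
    return bag, y[bag]


def gini_impurity(counts) -> float:
    """1 − Σ pᵢ² over class counts at a node."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 - (p**2).sum())


def gini_decrease(parent, left, right) -> float:
    """Impurity decrease of one split, weighted by child fractions."""
    parent = np.asarray(parent, dtype=float)
    n = parent.sum()
    nl, nr = np.sum(left), np.sum(right)
    if nl + nr != n:
        raise ValueError("children must partition the parent")
    return (
        gini_impurity(parent)
        - nl / n * gini_impurity(left)
        - nr / n * gini_impurity(right)
    )


def fit_tree(
    X: np.ndarray, y: np.ndarray, config: ForestConfig, tree_seed
) -> DecisionTreeClassifier:
    """Grow one CART tree on a bag: Gini splits, mtry features per node."""
    if len(y) == 0:
        raise ValueError("empty bag")
    p = X.shape[1]
    mtry = config.mtry or max(1, int(np.sqrt(p)))
    rng = np.random.default_rng(tree_seed)
    sk_seed = int(rng.integers(0, 2**31 - 1))
    tree = DecisionTreeClassifier(
        criterion="gini",
        max_features=min(mtry, p),
        min_samples_leaf=config.min_node_size,
        max_depth=config.max_depth,
        random_state=sk_seed,
    )
    tree.fit(X, y)
    return tree


def fit_forest(
    X: pd.DataFrame, labels: pd.Series, config: ForestConfig | None = None
) -> ForestModel:
    """Fit the PU ensemble.

    ``X`` is the complete encoded matrix over the whole gene universe
    (training and non-training tiers alike); ``labels`` covers the training
    genes only (TSG/OG/BG).  Tree ``t`` derives its seed from the master seed
    and ``t`` via a counter-based scheme, so any tree can be rebuilt in
    isolation and parallel execution cannot change results.
    """
    config = config or ForestConfig()
    if X.isna().any().any():
        raise ValueError("X must be complete (impute first)")
    missing = labels.index.difference(X.index)
    if len(missing):
        raise KeyError(f"labels for genes absent from X: {list(missing)[:5]}")
    # positions of training genes within the universe matrix
    pos_in_X = pd.Series(np.arange(len(X)), index=X.index)
    train_positions = pos_in_X[labels.index].to_numpy()
    Xv = X.to_numpy(dtype=float)
    class_to_idx = {c: i for i, c in enumerate(CLASSES)}

    trees: list[TreeRecord] = []
    for t in range(config.n_trees):
        bag_seed, grow_seed = _tree_seed(config.seed, t).spawn(2)
        bag_local, y_bag = sample_training_set(labels, config, bag_seed)
        bag_universe = train_positions[bag_local]
        tree = fit_tree(Xv[bag_universe], y_bag, config, grow_seed)
        order = np.array([class_to_idx[c] for c in tree.classes_])
        trees.append(
            TreeRecord(tree=tree, in_bag_genes=bag_universe, class_order=order)
        )
    return ForestModel(
        trees=trees,
        config=config,
        gene_index=X.index,
        feature_names=list(X.columns),
    )


def oob_posteriors(model: ForestModel, X: pd.DataFrame) -> PosteriorTable:
    """Average leaf class proportions over each gene's out-of-bag trees.

    ``X`` must cover every gene of the model's universe with the model's
    feature columns.  Genes appearing in a tree's bag (with any multiplicity)
    are excluded from that tree's votes.  A gene with no out-of-bag tree gets
    an undefined posterior (NaN) and is excluded from ranking.
    """
    if list(X.columns) != model.feature_names:
        X = X[model.feature_names]
    if not X.index.equals(model.gene_index):
        X = X.reindex(model.gene_index)
        if X.isna().any().any():
            raise KeyError("X does not cover the model's gene universe")
    Xv = X.to_numpy(dtype=float)
    n = len(X)
    sums = np.zeros((n, len(CLASSES)))
    counts = np.zeros(n, dtype=int)
    for rec in model.trees:
        proba = rec.tree.predict_proba(Xv)
        full = np.zeros((n, len(CLASSES)))
        full[:, rec.class_order] = proba
        oob_mask = np.ones(n)
        oob_mask[rec.in_bag_genes] = 0.0
        sums += full * oob_mask[:, None]
        counts += oob_mask.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = sums / counts[:, None]
    table = pd.DataFrame(
        post, index=model.gene_index, columns=[f"P_{c}" for c in CLASSES]
    )
    table["n_oob_trees"] = counts
    table["driver_score"] = table["P_TSG"] + table["P_OG"]
    defined = table["n_oob_trees"] > 0
    if (~defined).any():
        import warnings

        warnings.warn(
            f"{int((~defined).sum())} genes have no out-of-bag tree; "
            "posteriors undefined",
            stacklevel=2,
        )
    # stable sort + lexicographic pre-sort gives deterministic tie-breaks
    order = (
        table.loc[defined]
        .sort_index()
        .sort_values("driver_score", ascending=False, kind="mergesort")
    )
    table["rank"] = pd.Series(
        np.arange(1, defined.sum() + 1), index=order.index
    ).reindex(table.index)
    return PosteriorTable(table=table)


def rank_genes(posteriors: PosteriorTable, mode: str = "driver") -> list[str]:
    """Ordered gene list by the selected posterior score.

    ``mode`` ∈ {driver, TSG, OG}; driver uses P_TSG + P_OG.  Descending
    score, ties broken lexicographically by gene_id; undefined posteriors
    excluded.
    """
    score_col = {"driver": "driver_score", "TSG": "P_TSG", "OG": "P_OG"}[mode]
    t = posteriors.defined().sort_index()
    t = t.sort_values(score_col, ascending=False, kind="mergesort")
    return list(t.index)


def feature_importance(model: ForestModel) -> pd.Series:
    """Total Gini impurity decrease per feature, averaged over trees.

    Unnormalized: each tree contributes the sum over its internal nodes of
    (weighted node impurity − weighted child impurities), attributed to the
    splitting feature; features never selected score exactly 0.
    """
    total = np.zeros(len(model.feature_names))
    for rec in model.trees:
        t = rec.tree.tree_
        left, right = t.children_left, t.children_right
        w = t.weighted_n_node_samples
        imp = t.impurity
        root_w = w[0]
        internal = left != -1
        for node in np.flatnonzero(internal):
            dec = (
                w[node] * imp[node]
                - w[left[node]] * imp[left[node]]
                - w[right[node]] * imp[right[node]]
            ) / root_w
            total[t.feature[node]] += dec
    return pd.Series(total / model.n_trees, index=model.feature_names,
                     name="gini_importance")
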
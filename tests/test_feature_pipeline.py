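"""Feature derivation and the cleaning stages against hand oracles."""

import itertools
from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from driverforest.feature_pipeline import (
    FeatureTable,
    FilterConfig,
    betweenness,
    encode_features,
    genomic_density,
    impute_knn,
    normalize_ptm,
    ppi_count,
    prepare_features,
    remove_correlated,
    remove_sparse,
    tissue_summary,
)


def make_table(df: pd.DataFrame, **types) -> FeatureTable:
    defaults = {c: types.get(c, "continuous") for c in df.columns}
    return FeatureTable(data=df, types=defaults)


class TestGenomicDensity:
    def test_hand_enumerated_three_genes(self):
        coords = pd.DataFrame(
            {"chrom": ["c1"] * 3, "center_bp": [1.0e6, 2.0e6, 10.0e6]},
            index=["a", "b", "c"],
        )
        d = genomic_density(coords, window_bp=4e6)
        # counts 2,2,1 (self included); mean 5/3
        assert d.tolist() == pytest.approx([1.2, 1.2, 0.6])

    def test_single_gene_and_identical_centers(self):
        one = pd.DataFrame({"chrom": ["c1"], "center_bp": [5e6]}, index=["a"])
        assert genomic_density(one).iloc[0] == pytest.approx(1.0)
        same = pd.DataFrame(
            {"chrom": ["c1"] * 4, "center_bp": [7e6] * 4}, index=list("abcd")
        )
        assert genomic_density(same).tolist() == pytest.approx([1.0] * 4)

    def test_chromosomes_do_not_mix_and_missing_centers_propagate(self):
        coords = pd.DataFrame(
            {"chrom": ["c1", "c2", "c1"], "center_bp": [1e6, 1e6, np.nan]},
            index=["a", "b", "c"],
        )
        d = genomic_density(coords)
        assert d["a"] == d["b"]  # each alone on its chromosome
        assert np.isnan(d["c"])

    def test_mean_is_one_by_construction(self, small_universe):
        d = genomic_density(small_universe.coords)
        assert d.mean() == pytest.approx(1.0)


class TestSimpleDerivations:
    def test_ppi_count_mean_and_single_source(self):
        a = pd.Series([3.0, 0.0, 7.0, np.nan], index=list("abcd"))
        b = pd.Series([5.0, 0.0, np.nan, np.nan], index=list("abcd"))
        got = ppi_count(a, b)
        assert got["a"] == 4.0
        assert got["b"] == 0.0
        assert got["c"] == 7.0  # mean of the available source
        assert np.isnan(got["d"])

    def test_tissue_summary_fixture_and_degenerate_rows(self):
        expr = pd.DataFrame(
            {
                "t1": [1.0, 2.0, np.nan],
                "t2": [2.0, 2.0, np.nan],
                "t3": [3.0, 2.0, np.nan],
            },
            index=["x", "const", "empty"],
        )
        out = tissue_summary(expr)
        assert out.loc["x", "expression_median"] == 2.0
        assert out.loc["x", "expression_variation"] == pytest.approx(2.0)  # mean/sd
        assert np.isnan(out.loc["const", "expression_variation"])  # sd == 0
        assert np.isnan(out.loc["empty", "expression_median"])

    def test_normalize_ptm_elementwise_oracle(self):
        counts = pd.DataFrame(
            {"acetyl": [10, 0, 4], "phospho": [3, 5, 0]}, index=list("abc")
        )
        lengths = pd.Series([1000.0, 500.0, np.nan], index=list("abc"))
        out = normalize_ptm(counts, lengths)
        for g, c in itertools.product("ab", counts.columns):
            assert out.loc[g, f"ptm_rate_{c}"] == counts.loc[g, c] / lengths[g]
        assert out.loc["c"].isna().all()


def brute_betweenness(edges):
    """All-pairs shortest-path enumeration by BFS, for graphs <= 12 nodes."""
    adj = defaultdict(set)
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    nodes = sorted(adj)
    score = dict.fromkeys(nodes, 0.0)

    def all_shortest_paths(s, t):
        # BFS layers, then recursive path reconstruction
        from collections import deque

        dist = {s: 0}
        q = deque([s])
        while q:
            x = q.popleft()
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    q.append(y)
        if t not in dist:
            return []
        paths = []

        def back(node, path):
            if node == s:
                paths.append([s, *reversed(path)])
                return
            for y in adj[node]:
                if dist.get(y) == dist[node] - 1:
                    back(y, path + [node])

        back(t, [])
        return paths

    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for interior in p[1:-1]:
                score[interior] += 1.0 / len(paths)
    return pd.Series(score)


class TestBetweenness:
    def test_path_and_star(self):
        path = betweenness([("a", "b"), ("b", "c")])
        assert path["b"] == 1.0 and path["a"] == 0.0 and path["c"] == 0.0
        star = betweenness([("hub", f"l{i}") for i in range(4)])
        assert star["hub"] == 6.0  # C(4,2) pairs
        assert all(star[f"l{i}"] == 0.0 for i in range(4))

    def test_self_loops_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            out = betweenness([("a", "a"), ("a", "b"), ("b", "c")])
        assert out["b"] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(rng.integers(5, 13))]
        edges = [
            (a, b)
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.35
        ]
        if not edges:
            edges = [(nodes[0], nodes[1])]
        got = betweenness(edges)
        expected = brute_betweenness(edges)
        for node in expected.index:
            assert got[node] == pytest.approx(expected[node], abs=1e-9)


class TestRemoveSparse:
    def test_sparse_criteria_require_both_conditions(self):
        n = 100
        df = pd.DataFrame(
            {
                "sparse": ["A"] * 99 + ["B"],            # ratio 99, unique 2%
                "balanced": ["A", "B"] * 50,             # ratio 1
                "continuous": np.arange(n, dtype=float), # unique 100%
            },
            index=[f"g{i}" for i in range(n)],
        )
        table = FeatureTable(
            data=df,
            types={"sparse": "categorical", "balanced": "categorical",
                   "continuous": "continuous"},
        )
        filtered, report = remove_sparse(table)
        assert list(filtered.data.columns) == ["balanced", "continuous"]
        assert report.feature.tolist() == ["sparse"]

    def test_missing_counts_as_a_value(self):
        n = 200
        col = pd.Series([1.0] * n)
        col.iloc[:8] = np.nan  # 8 missing cells: second most common "value"
        df = pd.DataFrame({"f": col.values}, index=[f"g{i}" for i in range(n)])
        table = make_table(df, f="continuous")
        _, report = remove_sparse(table)
        # ratio 192/8 = 24 < 97/3 → kept despite 1% unique values
        assert report.empty

    def test_single_valued_column_removed(self):
        df = pd.DataFrame(
            {"const": [3.0] * 50, "ok": np.arange(50.0)},
            index=[f"g{i}" for i in range(50)],
        )
        filtered, report = remove_sparse(make_table(df))
        assert list(filtered.data.columns) == ["ok"]
        assert np.isinf(report.loc[0, "freq_ratio"])


class TestRemoveCorrelated:
    def test_exact_duplicate_pair_loses_exactly_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=300)
        df = pd.DataFrame(
            {"f": base, "f_copy": base.copy(), "other": rng.normal(size=300)},
            index=[f"g{i}" for i in range(300)],
        )
        filtered, report = remove_correlated(make_table(df))
        assert len({"f", "f_copy"} & set(filtered.data.columns)) == 1
        assert "other" in filtered.data.columns
        assert len(report) == 1

    def test_independent_features_survive(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            rng.normal(size=(500, 2)), columns=["a", "b"],
            index=[f"g{i}" for i in range(500)],
        )
        filtered, report = remove_correlated(make_table(df))
        assert list(filtered.data.columns) == ["a", "b"]

    def test_postcondition_no_pair_above_threshold(self, rng):
        base = rng.normal(size=(200, 3))
        df = pd.DataFrame(base, columns=["a", "b", "c"],
                          index=[f"g{i}" for i in range(200)])
        df["a2"] = df["a"] + rng.normal(scale=1e-6, size=200)
        df["b2"] = -df["b"]
        filtered, _ = remove_correlated(make_table(df))
        corr = filtered.data.corr(method="spearman").abs()
        np.fill_diagonal(corr.values, 0)
        assert corr.max().max() <= 0.95

    def test_constant_column_warns(self):
        df = pd.DataFrame(
            {"const": np.ones(50), "x": np.arange(50.0)},
            index=[f"g{i}" for i in range(50)],
        )
        with pytest.warns(UserWarning):
            filtered, _ = remove_correlated(make_table(df))
        assert "const" in filtered.data.columns  # zero correlation: kept


class TestImputeKnn:
    def test_complete_table_unchanged(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"),
                          index=[f"g{i}" for i in range(20)])
        table = make_table(df)
        out = impute_knn(table)
        pd.testing.assert_frame_equal(out.data, df)

    def test_identical_genes_fill_shared_value(self):
        df = pd.DataFrame(
            {"a": [1.0] * 6, "b": [2.0] * 6}, index=[f"g{i}" for i in range(6)]
        )
        df.loc["g0", "b"] = np.nan
        out = impute_knn(make_table(df))
        assert out.data.loc["g0", "b"] == 2.0

    def test_median_fallback_when_neighbors_all_missing(self):
        # gene g0 and its 5 nearest neighbors (identical in 'a') all miss 'b';
        # remaining genes are far away in 'a' but observe 'b'
        a = [0.0] * 6 + [100.0, 101.0, 102.0, 103.0, 104.0]
        b = [np.nan] * 6 + [10.0, 11.0, 12.0, 13.0, 14.0]
        df = pd.DataFrame({"a": a, "b": b}, index=[f"g{i}" for i in range(11)])
        out = impute_knn(make_table(df))
        assert out.data.loc["g0", "b"] == 12.0  # column median

    def test_observed_cells_bit_identical(self, small_universe):
        table = small_universe.features
        sub = table.subset([c for c in table.data.columns
                            if table.types[c] != "categorical"][:8])
        out = impute_knn(sub)
        observed = sub.data.notna()
        assert out.data.notna().all().all()
        for col in sub.data.columns:
            orig = sub.data.loc[observed[col], col]
            assert (out.data.loc[orig.index, col] == orig).all()

    def test_all_missing_feature_rejected(self):
        df = pd.DataFrame(
            {"a": np.arange(10.0), "b": [np.nan] * 10},
            index=[f"g{i}" for i in range(10)],
        )
        with pytest.raises(ValueError, match="missing in every gene"):
            impute_knn(make_table(df))


class TestEncodeFeatures:
    def test_one_hot_and_round_trip(self):
        df = pd.DataFrame(
            {
                "x": [0.5, 1.5, 2.5],
                "flag": [0.0, 1.0, 0.0],
                "ess": ["essential", "other", "phenotype"],
            },
            index=list("abc"),
        )
        table = FeatureTable(
            data=df, types={"x": "continuous", "flag": "binary",
                            "ess": "categorical"}
        )
        X, cmap = encode_features(table)
        onehot_cols = [c for c in X.columns if c.startswith("ess=")]
        assert len(onehot_cols) == 3
        assert (X[onehot_cols].sum(axis=1) == 1.0).all()
        assert set(cmap["feature"]) == {"x", "flag", "ess"}

    def test_pure_continuous_is_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}, index=["x", "y"])
        X, _ = encode_features(make_table(df))
        pd.testing.assert_frame_equal(X, df)

    def test_incomplete_table_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan]}, index=["x", "y"])
        with pytest.raises(ValueError):
            encode_features(make_table(df))


class TestPipelineOrder:
    def test_planted_columns_removed_and_output_complete(self, small_matrix,
                                                         small_universe):
        X, cmap, report = small_matrix
        removed = set(report.feature)
        assert {"sparse_00", "sparse_01"} <= removed
        dup_sources = {f"cont_{j:02d}" for j in range(2)}
        for dup in (f"dup_of_cont_{j:02d}" for j in range(2)):
            assert dup in removed or (
                {dup} | dup_sources
            ) & set(X.columns)  # exactly one survivor of each pair
        assert not X.isna().any().any()
        # filters never created columns: every encoded column maps back
        src = set(cmap["feature"])
        assert src <= set(small_universe.features.data.columns)
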
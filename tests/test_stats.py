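import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrflux.stats import (
    PathwaySet,
    StatsError,
    anova_rank,
    correlation_difference,
    hierarchical_order,
    ora_hypergeometric,
    pca,
    read_gmt,
    write_gmt,
    zscale,
)
from oracles import hypergeom_tail_enumeration


def table_from(values, columns=None, prefix="s"):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"m{j}" for j in range(values.shape[1])]
    index = [f"{prefix}{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=index, columns=columns)


class TestZscale:
    def test_per_metabolite_columns_standardized(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.uniform(0, 5, size=(10, 4)))
        z = zscale(t)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(1)
        t = table_from(rng.normal(size=(8, 3)))
        z = zscale(t)
        np.testing.assert_allclose(zscale(z).to_numpy(), z.to_numpy(), atol=1e-12)

    def test_constant_column_zeroed_with_warning(self):
        t = table_from([[1, 5], [1, 6], [1, 7]])
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscale(t)
        assert np.all(z["m0"] == 0)

    def test_global_mode_standardizes_whole_matrix(self):
        rng = np.random.default_rng(2)
        t = table_from(rng.uniform(0, 3, size=(6, 5)))
        z = zscale(t, mode="global").to_numpy()
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(StatsError):
            zscale(table_from([[1, 2]]))


class TestAnovaRank:
    def test_identical_group_distributions_give_zero_f(self):
        t = table_from([[1], [2], [1], [2]])
        labels = pd.Series(["a", "a", "b", "b"], index=t.index)
        res = anova_rank(t, labels)
        assert res["f_statistic"].iloc[0] == 0.0

    def test_f_matches_sums_of_squares_formula(self):
        # two classes with means 0 and 1, small within-group spread eps
        eps = 0.1
        a = np.array([0 - eps, 0.0, 0 + eps])
        b = np.array([1 - eps, 1.0, 1 + eps])
        t = table_from(np.concatenate([a, b])[:, None])
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=t.index)
        res = anova_rank(t, labels)
        # textbook one-way ANOVA from sums of squares
        grand = np.concatenate([a, b]).mean()
        ss_between = 3 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_expected = (ss_between / 1) / (ss_within / 4)
        assert res["f_statistic"].iloc[0] == pytest.approx(f_expected, rel=1e-12)

    def test_ranks_descending_and_panel_rule(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(8, 3))
        base[4:, 0] += 10.0  # strong effect on m0 only
        t = table_from(base)
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=t.index)
        res = anova_rank(t, labels, threshold=5.0)
        assert res["metabolite"].iloc[0] == "m0"
        assert list(res["rank"]) == [1, 2, 3]
        assert bool(res["selected"].iloc[0])
        assert res["f_statistic"].is_monotonic_decreasing

    def test_small_class_rejected_by_name(self):
        t = table_from([[1], [2], [3]])
        labels = pd.Series(["a", "a", "lonely"], index=t.index)
        with pytest.raises(StatsError, match="lonely"):
            anova_rank(t, labels)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(min_value=0.1, max_value=50, allow_nan=False),
        b=st.floats(min_value=-20, max_value=20, allow_nan=False),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        t = table_from(rng.normal(size=(9, 2)))
        labels = pd.Series(["x"] * 3 + ["y"] * 3 + ["z"] * 3, index=t.index)
        f0 = anova_rank(t, labels).set_index("metabolite")["f_statistic"]
        t2 = t.copy()
        t2["m1"] = a * t2["m1"] + b
        f1 = anova_rank(t2, labels).set_index("metabolite")["f_statistic"]
        assert f1["m1"] == pytest.approx(f0["m1"], rel=1e-9)


class TestPca:
    def test_collinear_data_explained_by_first_component(self):
        x = np.linspace(0, 1, 10)
        X = np.column_stack([x, 2 * x])
        scores, loadings, explained = pca(X)
        assert explained[0] == pytest.approx(1.0)
        assert explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 5))
        scores, loadings, explained = pca(X)
        recon = scores @ loadings.T + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-9)
        assert explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(explained) <= 1e-12)

    def test_separated_clusters_split_on_pc1(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.2, size=(10, 4))
        b = rng.normal(0, 0.2, size=(10, 4)) + 5.0
        X = np.vstack([a, b])
        scores, _, _ = pca(X, 2)
        labels = [0] * 10 + [1] * 10
        assert silhouette_score(scores[:, :1], labels) > 0

    def test_component_bounds_checked(self):
        with pytest.raises(StatsError):
            pca(np.eye(3), 4)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 3))
        _, loadings1, _ = pca(X)
        _, loadings2, _ = pca(X.copy())
        np.testing.assert_array_equal(loadings1, loadings2)
        for k in range(loadings1.shape[1]):
            assert loadings1[np.abs(loadings1[:, k]).argmax(), k] > 0


class TestHierarchicalOrder:
    def test_two_items(self):
        t = table_from([[0, 1], [1, 0]])
        assert hierarchical_order(t, axis="metabolites") == [0, 1]

    def test_identical_items_adjacent(self):
        t = table_from(np.array([[1.0, 5.0, 1.0], [2.0, 9.0, 2.0], [0.0, 4.0, 0.0]]))
        order = hierarchical_order(t, axis="metabolites")
        pos = {m: i for i, m in enumerate(order)}
        assert abs(pos[0] - pos[2]) == 1

    @pytest.mark.parametrize("axis,n", [("metabolites", 6), ("samples", 9)])
    def test_order_is_permutation(self, axis, n):
        rng = np.random.default_rng(9)
        t = table_from(rng.normal(size=(9, 6)))
        order = hierarchical_order(t, axis=axis, distance="correlation", linkage_method="complete")
        assert sorted(order) == list(range(n))


class TestCorrelationDifference:
    def test_identical_tables_give_zero_map(self):
        rng = np.random.default_rng(10)
        t = table_from(rng.normal(size=(6, 4)))
        delta = correlation_difference(t, t.copy())
        np.testing.assert_allclose(delta.to_numpy(), 0, atol=1e-12)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(11)
        a = table_from(rng.normal(size=(8, 4)))
        b = table_from(rng.normal(size=(7, 4)))
        d_ab = correlation_difference(a, b).to_numpy()
        d_ba = correlation_difference(b, a).to_numpy()
        np.testing.assert_allclose(d_ab, -d_ba, atol=1e-12)

    def test_planted_correlation_detected(self):
        rng = np.random.default_rng(12)
        n = 50
        x = rng.normal(size=n)
        a = table_from(np.column_stack([x, x + 1e-9 * rng.normal(size=n), rng.normal(size=n)]))
        b = table_from(rng.normal(size=(n, 3)))
        delta = correlation_difference(a, b)
        # planted perfect correlation in A: delta equals exactly 1 - r_B
        r_b = np.corrcoef(b["m0"], b["m1"])[0, 1]
        assert delta.iloc[0, 1] == pytest.approx(1.0 - r_b, abs=1e-9)
        assert delta.iloc[0, 1] > 0.5

    def test_zero_variance_marked_undefined(self):
        a = table_from([[1, 2], [1, 3], [1, 4]])
        b = table_from([[0, 1], [2, 5], [1, 3]])
        with pytest.warns(UserWarning, match="zero-variance"):
            delta = correlation_difference(a, b)
        assert np.isnan(delta.iloc[0, 1])

    def test_mismatched_columns_rejected(self):
        a = table_from([[1, 2], [3, 4], [5, 6]])
        b = table_from([[1, 2], [3, 4], [5, 6]], columns=["x", "y"])
        with pytest.raises(StatsError):
            correlation_difference(a, b)


class TestOra:
    def test_selected_equals_universe_forces_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        pws = [PathwaySet("p1", frozenset(list(universe)[:4]))]
        res = ora_hypergeometric(universe, pws, universe)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_full_overlap_case(self):
        universe = {f"g{i}" for i in range(10)}
        members = frozenset(f"g{i}" for i in range(5))
        res = ora_hypergeometric(set(members), [PathwaySet("p", members)], universe)
        assert res["p_value"].iloc[0] == pytest.approx(1 / 252, rel=1e-12)
        assert res["overlap"].iloc[0] == 5

    def test_disjoint_pathway_p_one(self):
        universe = {"a", "b", "c", "d"}
        res = ora_hypergeometric({"a"}, [PathwaySet("p", frozenset({"zzz"}))], universe)
        assert res["overlap"].iloc[0] == 0
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self):
        for N in (5, 8, 12):
            universe = {f"g{i}" for i in range(N)}
            ids = sorted(universe)
            for K, n in itertools.product((1, N // 2, N - 1), repeat=2):
                pw = PathwaySet("p", frozenset(ids[:K]))
                selected = set(ids[-n:])
                res = ora_hypergeometric(selected, [pw], universe)
                k = len(pw.members & selected)
                expected = hypergeom_tail_enumeration(N, K, n, k)
                assert res["p_value"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_input_validation(self):
        with pytest.raises(StatsError):
            ora_hypergeometric({"a"}, [], set())
        with pytest.raises(StatsError):
            ora_hypergeometric({"zzz"}, [], {"a"})

    def test_benjamini_hochberg_option(self):
        universe = {f"g{i}" for i in range(10)}
        ids = sorted(universe)
        pws = [PathwaySet("p1", frozenset(ids[:5])), PathwaySet("p2", frozenset(ids[5:]))]
        res = ora_hypergeometric(set(ids[:5]), pws, universe, benjamini_hochberg=True)
        assert "p_adjusted" in res.columns
        assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()


def test_gmt_round_trip(tmp_path):
    pws = [PathwaySet("alpha", frozenset({"a", "b"})), PathwaySet("beta", frozenset({"c"}))]
    p = tmp_path / "sets.gmt"
    write_gmt(pws, p)
    back = read_gmt(p)
    assert {(x.name, x.members) for x in back} == {(x.name, x.members) for x in pws}
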
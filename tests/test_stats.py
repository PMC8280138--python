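import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wnnets import (
    ComparisonDesign,
    bh_adjust,
    detect_sfcp,
    detect_ssp,
    difference_summary,
    high_degree_sets,
    set_intersections,
    ssp_subnetwork,
)


def degree_frame(rng, n_proteins, design, shift=None):
    """iid standard-normal 'degrees' with an optional treated-group shift."""
    samples = design.sample_ids
    values = rng.normal(10.0, 1.0, size=(n_proteins, len(samples)))
    frame = pd.DataFrame(
        values, index=[f"P{i}" for i in range(n_proteins)], columns=samples
    )
    if shift:
        protein, delta = shift
        treated = design.samples_of(design.comparisons[0][0])
        frame.loc[protein, treated] += delta
    return frame


class TestBhAdjust:
    def test_hand_applied_step_up(self):
        # p_(i) * m / i then running minimum from the top:
        # (0.01*3/1, 0.02*3/2, 0.03*3/3) -> (0.03, 0.03, 0.03)
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_second_hand_example(self):
        assert bh_adjust([0.01, 0.04, 0.9]) == pytest.approx([0.03, 0.06, 0.9])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42]) == pytest.approx([0.42])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_rank_monotone(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDetectSsp:
    def test_identical_groups_yield_no_ssp(self, two_group_design, rng):
        half = rng.normal(10, 1, size=(20, 6))
        frame = pd.DataFrame(
            np.hstack([half, half]),
            index=[f"P{i}" for i in range(20)],
            columns=two_group_design.sample_ids,
        )
        table = detect_ssp(frame, two_group_design)
        assert not table["is_ssp"].any()
        assert (table["p_adjusted"] == 1.0).all()

    def test_planted_ten_sigma_shift_detected(self, two_group_design, rng):
        frame = degree_frame(rng, 50, two_group_design, shift=("P7", 10.0))
        table = detect_ssp(frame, two_group_design)
        flagged = set(table.loc[table["is_ssp"], "protein"])
        assert flagged == {"P7"}

    def test_small_group_rejected(self):
        design = ComparisonDesign(
            groups={"a": ["s1"], "b": ["s2", "s3"]}, comparisons=(("a", "b"),)
        )
        frame = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["P0"], columns=["s1", "s2", "s3"]
        )
        with pytest.raises(ValueError, match="at least 2"):
            detect_ssp(frame, design)

    def test_scale_invariance_of_pvalues(self, two_group_design, rng):
        frame = degree_frame(rng, 15, two_group_design)
        p1 = detect_ssp(frame, two_group_design)["pvalue"]
        p2 = detect_ssp(0.003 * frame, two_group_design)["pvalue"]
        np.testing.assert_allclose(p1, p2, rtol=1e-9)

    def test_invariant_under_row_and_column_reordering(self, two_group_design, rng):
        frame = degree_frame(rng, 12, two_group_design, shift=("P3", 8.0))
        shuffled = frame.sample(frac=1, axis=0, random_state=7).sample(
            frac=1, axis=1, random_state=8
        )
        a = detect_ssp(frame, two_group_design).set_index("protein").sort_index()
        b = detect_ssp(shuffled, two_group_design).set_index("protein").sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_constant_groups(self, two_group_design):
        frame = pd.DataFrame(
            [[1.0] * 12, [1.0] * 6 + [2.0] * 6],
            index=["same", "diff"],
            columns=two_group_design.sample_ids,
        )
        table = detect_ssp(frame, two_group_design).set_index("protein")
        assert table.loc["same", "pvalue"] == 1.0
        assert table.loc["diff", "pvalue"] == 0.0

    def test_null_family_wise_rate_matches_alpha(self, two_group_design):
        # under the global null BH's P(any rejection) equals alpha;
        # 300 trials at alpha=0.1 should land well inside [0.03, 0.2]
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(300):
            frame = degree_frame(rng, 30, two_group_design)
            table = detect_ssp(frame, two_group_design)
            hits += int(table["is_ssp"].any())
        assert 0.03 < hits / 300 < 0.2


class TestDetectSfcp:
    def test_fourfold_change_flagged(self, two_group_design, rng):
        base = rng.uniform(0.9, 1.1, size=(5, 12))
        frame = pd.DataFrame(
            base, index=[f"P{i}" for i in range(5)],
            columns=two_group_design.sample_ids,
        )
        treated = two_group_design.samples_of("trt")
        frame.loc["P2", treated] *= 4.0
        table = detect_sfcp(frame, two_group_design).set_index("protein")
        assert table.loc["P2", "log2_fold_change"] == pytest.approx(2.0, abs=0.2)
        assert table.loc["P2", "is_sfcp"]
        assert not table.drop(index="P2")["is_sfcp"].any()

    def test_equal_means_never_flagged(self, two_group_design):
        frame = pd.DataFrame(
            np.ones((3, 12)), index=list("abc"), columns=two_group_design.sample_ids
        )
        table = detect_sfcp(frame, two_group_design)
        assert (table["log2_fold_change"] == 0).all()
        assert not table["is_sfcp"].any()

    def test_threshold_is_strict(self, two_group_design):
        # exactly 2-fold change (log2 fc == 1) does not pass a strict > 1
        frame = pd.DataFrame(
            [[1.0] * 6 + [2.0] * 6], index=["P0"], columns=two_group_design.sample_ids
        )
        table = detect_sfcp(frame, two_group_design)
        assert table.loc[0, "log2_fold_change"] == pytest.approx(1.0)
        assert not table.loc[0, "is_sfcp"]

    def test_nonpositive_weights_rejected(self, two_group_design):
        frame = pd.DataFrame(
            np.zeros((1, 12)), index=["P0"], columns=two_group_design.sample_ids
        )
        with pytest.raises(ValueError):
            detect_sfcp(frame, two_group_design)


class TestHighDegreeSets:
    def test_linear_interpolation_quantile(self):
        degrees = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0, 4.0], "s2": [1.0, 2.0, 3.0, 4.0]},
            index=list("abcd"),
        )
        result = high_degree_sets(degrees, {"g": ["s1", "s2"]}, q=0.75)
        assert result.thresholds["g"] == pytest.approx(3.25)
        assert result.sets["g"] == {"d"}

    def test_all_equal_means_empty_set(self):
        degrees = pd.DataFrame({"s1": [2.0, 2.0, 2.0]}, index=list("abc"))
        result = high_degree_sets(degrees, {"g": ["s1"]})
        assert result.sets["g"] == frozenset()

    def test_invalid_quantile_rejected(self):
        degrees = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            high_degree_sets(degrees, {"g": ["s1"]}, q=1.5)

    def test_set_size_bound_with_distinct_means(self, rng):
        p, q = 40, 0.75
        degrees = pd.DataFrame(
            {"s1": rng.permutation(p).astype(float)},
            index=[f"P{i}" for i in range(p)],
        )
        result = high_degree_sets(degrees, {"g": ["s1"]}, q=q)
        assert len(result.sets["g"]) <= int(np.ceil((1 - q) * p))


class TestDifferenceSummary:
    def _design(self):
        return ComparisonDesign(
            groups={
                "c1": ["a1"], "t1": ["b1"], "c2": ["a2"], "t2": ["b2"],
            },
            comparisons=(("t1", "c1"), ("t2", "c2")),
        )

    def test_absolute_differences_and_ratio(self):
        degrees = pd.DataFrame(
            {"a1": [1.0, 2.0], "b1": [2.0, 4.0], "a2": [1.0, 2.0], "b2": [1.5, 2.5]},
            index=["p", "q"],
        )
        summary = difference_summary(degrees, self._design())
        assert summary.per_protein["c1-t1"].tolist() == [1.0, 2.0]
        assert summary.global_mean["c1-t1"] == pytest.approx(1.5)
        assert summary.global_mean["c2-t2"] == pytest.approx(0.5)
        assert summary.ratio("c1-t1", "c2-t2") == pytest.approx(3.0)

    def test_identical_groups_zero_difference(self, two_group_design):
        degrees = pd.DataFrame(
            np.tile(np.arange(1.0, 4.0)[:, None], 12),
            index=list("abc"), columns=two_group_design.sample_ids,
        )
        summary = difference_summary(degrees, two_group_design)
        assert summary.global_mean["ctrl-trt"] == 0.0


class TestSetIntersections:
    def test_two_overlapping_sets(self):
        result = set_intersections({"S1": {"A", "B"}, "S2": {"B", "C"}})
        rows = result.exclusive.set_index(["S1", "S2"])["count"]
        assert rows.loc[(True, False)] == 1
        assert rows.loc[(False, True)] == 1
        assert rows.loc[(True, True)] == 1
        assert result.set_sizes == {"S1": 2, "S2": 2}

    def test_identical_sets_single_pattern(self):
        result = set_intersections({"S1": {"A", "B"}, "S2": {"A", "B"}})
        rows = result.exclusive.set_index(["S1", "S2"])["count"]
        assert rows.loc[(True, True)] == 2
        assert rows.loc[(True, False)] == 0

    def test_exclusive_counts_partition_the_union(self, rng):
        universe = [f"P{i}" for i in range(20)]
        sets = {
            f"S{k}": set(rng.choice(universe, size=rng.integers(1, 15), replace=False))
            for k in range(4)
        }
        result = set_intersections(sets)
        union = set().union(*sets.values())
        assert result.exclusive["count"].sum() == len(union)
        # cross-check one pattern by brute force membership enumeration
        for _, row in result.exclusive.iterrows():
            expected = {
                p for p in union
                if all((p in sets[name]) == row[name] for name in sets)
            }
            assert row["count"] == len(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            set_intersections({})


class TestSspSubnetwork:
    def test_empty_ssp_set_gives_empty_graph(self, path_graph):
        sub = ssp_subnetwork(path_graph, set())
        assert sub.number_of_nodes() == 0

    def test_star_centre_pulls_in_all_leaves(self):
        star = nx.star_graph(4)
        sub = ssp_subnetwork(star, {0}, sfcps={1})
        assert set(sub.nodes) == {0, 1, 2, 3, 4}
        assert sub.nodes[0]["role"] == "ssp"
        assert sub.nodes[1]["role"] == "sfcp"
        assert sub.nodes[2]["role"] == "contributor"

    def test_protein_in_both_sets_is_both(self, path_graph):
        sub = ssp_subnetwork(path_graph, {"b"}, sfcps={"b", "a"})
        assert sub.nodes["b"]["role"] == "both"
        assert sub.nodes["a"]["role"] == "sfcp"

    def test_unknown_ssp_rejected(self, path_graph):
        with pytest.raises(ValueError, match="zz"):
            ssp_subnetwork(path_graph, {"zz"})
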
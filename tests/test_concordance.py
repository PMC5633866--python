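"""Concordance engine: wCV, clique grouping, references, differences, tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcconcord.concordance import (
    GroupAssignment,
    WCVMatrix,
    bias_vs_adc_regression,
    consensus_reference,
    find_groups,
    intergroup_stats,
    pairwise_wcv,
    percent_difference,
    percent_differences,
    validate_table,
    wcv_matrix,
)


def make_table(values_by_impl: dict[str, list[float]], metric="ADC4") -> pd.DataFrame:
    """Long table with one dataset and one ROI per list position."""
    rows = []
    for impl, vals in values_by_impl.items():
        for k, v in enumerate(vals):
            rows.append({"implementation": impl, "dataset": f"d{k // 2}",
                         "roi": f"r{k % 2}", "metric": metric, "value": v})
    return pd.DataFrame(rows)


class TestPairwiseWCV:
    def test_identical_vectors_give_zero(self):
        t = make_table({"a": [1000.0, 1100.0], "b": [1000.0, 1100.0]})
        assert pairwise_wcv(t, "a", "b") == 0.0

    def test_direct_formula_evaluation(self):
        # mean of [(x-y)^2/2] / [((x+y)/2)^2] over the two pairs -> 0.70714%
        t = make_table({"a": [1000.0, 1100.0], "b": [1010.0, 1089.0]})
        assert pairwise_wcv(t, "a", "b") == pytest.approx(0.70714, abs=1e-4)

    def test_constant_ratio_closed_form(self):
        """For y = r*x the wCV is exactly 100*sqrt(2)*|r-1|/(1+r) %."""
        r = 1.001
        x = np.array([900.0, 1100.0, 1500.0, 700.0])
        t = make_table({"a": list(x), "b": list(r * x)})
        w = pairwise_wcv(t, "a", "b")
        assert w == pytest.approx(100 * np.sqrt(2) * (r - 1) / (1 + r), abs=1e-9)
        assert w == pytest.approx(0.1 / np.sqrt(2), abs=1e-4)

    @settings(max_examples=50, derandomize=True)
    @given(c=st.floats(1e-3, 1e3),
           vals=st.lists(st.floats(100, 3000), min_size=2, max_size=6))
    def test_scale_invariance(self, c, vals):
        x = np.array(vals)
        y = x * np.linspace(1.0, 1.01, x.size)
        t1 = make_table({"a": list(x), "b": list(y)})
        t2 = make_table({"a": list(c * x), "b": list(c * y)})
        assert pairwise_wcv(t1, "a", "b") == pytest.approx(
            pairwise_wcv(t2, "a", "b"), rel=1e-9)

    def test_no_shared_measurements_reported(self):
        t = pd.DataFrame([
            {"implementation": "a", "dataset": "d0", "roi": "r0",
             "metric": "ADC4", "value": 1.0},
            {"implementation": "b", "dataset": "d1", "roi": "r0",
             "metric": "ADC4", "value": 1.0},
        ])
        with pytest.raises(ValueError, match="no shared"):
            pairwise_wcv(t, "a", "b")

    def test_nonpositive_values_rejected(self):
        t = make_table({"a": [1.0, -1.0], "b": [1.0, 1.0]})
        with pytest.raises(ValueError, match="positive"):
            pairwise_wcv(t, "a", "b")

    def test_matrix_symmetric_zero_diagonal(self):
        t = make_table({"a": [1000.0, 1100.0], "b": [1010.0, 1089.0],
                        "c": [1002.0, 1098.0]})
        w = wcv_matrix(t)
        assert np.allclose(w.matrix, w.matrix.T)
        assert np.all(np.diag(w.matrix) == 0)
        assert np.all(w.matrix >= 0)


def brute_force_groups(impls, wcv, threshold):
    """Exhaustive oracle: all maximal all-pairs-below-threshold subsets."""
    ok = lambda s: all(wcv[a][b] < threshold
                       for a, b in itertools.combinations(s, 2))
    cliques = [frozenset(s)
               for n in range(1, len(impls) + 1)
               for s in itertools.combinations(impls, n) if ok(s)]
    return {c for c in cliques if not any(c < d for d in cliques)}


class TestFindGroups:
    def _matrix(self, impls, wcv):
        n = len(impls)
        m = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            m[i, j] = m[j, i] = wcv[impls[i]][impls[j]]
        return WCVMatrix(implementations=tuple(impls), matrix=m)

    def test_all_pairs_below_threshold_one_group(self):
        impls = ("a", "b", "c")
        wcv = {a: {b: 0.01 for b in impls} for a in impls}
        g = find_groups(self._matrix(impls, wcv), 0.1)
        assert g.n_groups == 1
        assert g.groups["A"] == impls
        assert g.ungrouped == ()

    def test_all_pairs_above_threshold_all_ungrouped(self):
        impls = ("a", "b", "c")
        wcv = {a: {b: 5.0 for b in impls} for a in impls}
        g = find_groups(self._matrix(impls, wcv), 0.1)
        assert g.n_groups == 0
        assert set(g.ungrouped) == set(impls)

    def test_block_diagonal_matches_exhaustive_oracle(self):
        """Two 3-cliques plus one outlier."""
        impls = ("a1", "a2", "a3", "b1", "b2", "b3", "x")
        wcv = {a: {} for a in impls}
        for a, b in itertools.combinations(impls, 2):
            same = a[0] == b[0] and a[0] in "ab"
            wcv[a][b] = wcv.setdefault(b, {})[a] = 0.02 if same else 3.0
        g = find_groups(self._matrix(impls, wcv), 0.1)
        assert g.n_groups == 2
        assert set(map(frozenset, g.groups.values())) == {
            frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"})}
        assert g.ungrouped == ("x",)
        oracle = brute_force_groups(impls, wcv, 0.1)
        multi = {c for c in oracle if len(c) >= 2}
        assert set(map(frozenset, g.groups.values())) <= multi

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_matrices_verified_against_oracle(self, seed):
        rng = np.random.default_rng(seed)
        impls = tuple(f"i{k}" for k in range(6))
        wcv = {a: {} for a in impls}
        for a, b in itertools.combinations(impls, 2):
            wcv[a][b] = wcv.setdefault(b, {})[a] = float(rng.choice([0.02, 3.0]))
        g = find_groups(self._matrix(impls, wcv), 0.1)
        oracle = {c for c in brute_force_groups(impls, wcv, 0.1) if len(c) >= 2}
        # every reported group is a maximal clique of the threshold graph
        for members in g.groups.values():
            assert frozenset(members) in oracle
        # groups are disjoint and cover everything not ungrouped
        all_members = [m for ms in g.groups.values() for m in ms]
        assert len(all_members) == len(set(all_members))
        assert set(all_members) | set(g.ungrouped) == set(impls)


class TestConsensusReference:
    def test_median_of_three(self):
        t = make_table({"a": [1.0], "b": [1.1], "c": [1.5]})
        ref = consensus_reference(t, mode="median_all")
        assert ref["reference"].iloc[0] == pytest.approx(1.1)

    def test_group_average_weights_groups_equally(self):
        t = make_table({"a1": [1.00], "a2": [1.00],
                        "b1": [1.03], "b2": [1.03], "b3": [1.03], "b4": [1.03]})
        groups = GroupAssignment(
            groups={"A": ("a1", "a2"), "B": ("b1", "b2", "b3", "b4")},
            ungrouped=(), threshold=0.1)
        ref = consensus_reference(t, groups, "group_average")
        # midpoint of the two group means, NOT the pooled mean (1.02)
        assert ref["reference"].iloc[0] == pytest.approx(1.015)

    def test_single_implementation_per_group(self):
        t = make_table({"a": [1.0], "b": [1.2]})
        groups = GroupAssignment(groups={"A": ("a",), "B": ("b",)},
                                 ungrouped=(), threshold=0.1)
        ref = consensus_reference(t, groups, "group_average")
        assert ref["reference"].iloc[0] == pytest.approx(1.1)

    def test_group_average_needs_two_groups(self):
        t = make_table({"a": [1.0], "b": [1.2]})
        groups = GroupAssignment(groups={"A": ("a", "b")}, ungrouped=(),
                                 threshold=0.1)
        with pytest.raises(ValueError, match="exactly 2 groups"):
            consensus_reference(t, groups, "group_average")


class TestPercentDifference:
    def test_examples(self):
        assert percent_difference(1.0, 1.0) == 0.0
        assert percent_difference(1.028, 1.0) == pytest.approx(2.8)
        assert percent_difference(0.986, 1.0) == pytest.approx(-1.4)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)

    def test_reference_self_difference_zero(self):
        t = make_table({"a": [1000.0, 1200.0], "b": [1000.0, 1200.0]})
        ref = consensus_reference(t, mode="median_all")
        merged = percent_differences(t, ref)
        assert np.allclose(merged["pct_diff"], 0.0)


class TestIntergroupStats:
    def test_constant_multiplier_gives_exact_mean_and_zero_sd(self):
        base = [1000.0, 1100.0, 1200.0, 900.0]
        t = make_table({"a1": base, "a2": base,
                        "b1": [1.028 * v for v in base],
                        "b2": [1.028 * v for v in base]})
        groups = GroupAssignment(groups={"A": ("a1", "a2"), "B": ("b1", "b2")},
                                 ungrouped=(), threshold=0.1)
        ig = intergroup_stats(t, groups)
        assert ig.mean_pct_diff == pytest.approx(2.8)
        assert ig.sd_pct_diff == pytest.approx(0.0, abs=1e-9)
        assert ig.p_value < 0.05

    def test_identical_groups_report_no_difference(self):
        base = [1000.0, 1100.0, 1200.0]
        t = make_table({"a": base, "b": base})
        groups = GroupAssignment(groups={"A": ("a",), "B": ("b",)},
                                 ungrouped=(), threshold=0.1)
        ig = intergroup_stats(t, groups)
        assert ig.mean_pct_diff == 0.0
        assert np.isnan(ig.p_value)


class TestRegression:
    def test_exact_line(self):
        x = np.array([0.5, 1.0, 1.5, 2.0])
        slope, r2 = bias_vs_adc_regression(x, x)   # y = x in 1e-3 units
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_response(self):
        slope, r2 = bias_vs_adc_regression([2.0, 2.0, 2.0], [0.5, 1.0, 1.5])
        assert slope == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_five_points_match_normal_equations(self):
        x = np.array([0.3, 0.7, 1.1, 1.6, 2.1])
        y = np.array([-0.5, 0.2, 0.1, 0.9, 1.4])
        slope, r2 = bias_vs_adc_regression(y, x)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        assert slope == pytest.approx(sxy / sxx, rel=1e-12)
        assert r2 == pytest.approx(sxy ** 2 / (sxx * syy), rel=1e-12)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bias_vs_adc_regression([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


def test_duplicate_rows_rejected():
    t = make_table({"a": [1.0]})
    with pytest.raises(ValueError, match="duplicate"):
        validate_table(pd.concat([t, t], ignore_index=True))
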
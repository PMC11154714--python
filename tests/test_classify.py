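"""Directional screens, BH control, six-set classification and contingency."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from irsplit.classify import (
    ScreenResult,
    bh_adjust,
    classify_sets,
    contingency,
    filter_expressed,
    rank_test_one_sided,
    run_screens,
    sample_odds_ratio,
    subset_percentages,
)


# ---------- independent oracles ----------

def rank_sum_p_enumeration(a, b, direction="greater"):
    """Exact one-sided rank-sum p by enumerating every group labeling."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n_a].sum()
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        s = ranks[list(idx)].sum()
        total += 1
        if (direction == "greater" and s >= obs - 1e-9) or (
            direction == "less" and s <= obs + 1e-9
        ):
            hits += 1
    return hits / total


def fisher_p_enumeration(table):
    """Two-sided Fisher p: sum of hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(N, c1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


# ---------- expression filter ----------

class TestFilterExpressed:
    def build(self, n_pos_nbc, n_pos_cll, n_nbc=9, n_cll=97):
        cols = [f"N{i}" for i in range(n_nbc)] + [f"C{i}" for i in range(n_cll)]
        groups = pd.Series(["NBC"] * n_nbc + ["CLL"] * n_cll, index=cols)
        row = [1.0] * n_pos_nbc + [0.0] * (n_nbc - n_pos_nbc)
        row += [1.0] * n_pos_cll + [0.0] * (n_cll - n_pos_cll)
        return pd.DataFrame([row], index=["t"], columns=cols), groups

    def test_retained_when_both_groups_pass(self):
        tpm, groups = self.build(6, 60)  # 0.667 and 0.619
        assert filter_expressed(tpm, groups) == ["t"]

    def test_dropped_when_one_group_fails(self):
        tpm, groups = self.build(5, 97)  # 0.556 in NBC
        assert filter_expressed(tpm, groups) == []

    def test_exact_boundary_inclusive(self):
        tpm, groups = self.build(6, 60, n_nbc=10, n_cll=100)  # exactly 0.60 both
        assert filter_expressed(tpm, groups, 0.60) == ["t"]

    def test_bad_threshold_rejected(self):
        tpm, groups = self.build(6, 60)
        with pytest.raises(ValueError):
            filter_expressed(tpm, groups, 0.0)


# ---------- rank test ----------

class TestRankTest:
    def test_small_exact_example(self):
        assert rank_test_one_sided([3, 4, 5], [1, 2], "greater") == pytest.approx(0.1)

    def test_fully_reversed_gives_one(self):
        assert rank_test_one_sided([1, 2], [3, 4], "greater") == pytest.approx(1.0)

    def test_identical_multisets_no_evidence(self):
        p = rank_test_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater")
        assert p >= 0.5

    def test_all_constant_degenerate(self):
        assert rank_test_one_sided([5, 5, 5], [5, 5], "greater") == 1.0
        assert rank_test_one_sided([5, 5, 5], [5, 5], "less") == 1.0

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            rank_test_one_sided([1], [2, 3], "greater")

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        n_a=st.integers(2, 5),
        n_b=st.integers(2, 5),
        data=st.data(),
        direction=st.sampled_from(["greater", "less"]),
    )
    def test_matches_enumeration_oracle(self, n_a, n_b, data, direction):
        """For pooled n <= 10 untied samples the p equals full enumeration."""
        vals = data.draw(
            st.lists(
                st.floats(-100, 100, allow_nan=False),
                min_size=n_a + n_b, max_size=n_a + n_b, unique=True,
            )
        )
        a, b = vals[:n_a], vals[n_a:]
        assert rank_test_one_sided(a, b, direction) == pytest.approx(
            rank_sum_p_enumeration(a, b, direction), abs=1e-12
        )


# ---------- BH ----------

class TestBhAdjust:
    def test_step_up_rejects_all(self):
        _, reject = bh_adjust([0.01, 0.02, 0.03, 0.04], 0.05)
        assert reject.all()

    def test_single_p_reduces_to_raw(self):
        _, reject = bh_adjust([0.04], 0.05)
        assert reject.all()

    def test_large_ps_none_rejected(self):
        q, reject = bh_adjust([0.9, 0.95], 0.05)
        assert not reject.any()
        assert np.allclose(sorted(q), [0.95, 0.95])

    def test_empty_input(self):
        q, reject = bh_adjust([], 0.05)
        assert q.size == 0 and reject.size == 0

    @settings(max_examples=50, derandomize=True)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_rejections_subset_and_monotone(self, ps):
        q, reject = bh_adjust(ps, 0.05)
        p = np.asarray(ps)
        assert (p[reject] <= 0.05 + 1e-12).all()
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


# ---------- classification ----------

def make_screen(rows: dict[str, dict]) -> ScreenResult:
    """ScreenResult from raw per-transcript p-values, BH-adjusting each screen."""
    table = pd.DataFrame(rows).T
    for col in ("p_ir_g1_gt_g2", "p_ir_g2_gt_g1", "p_expr_g1_gt_g2", "p_expr_g2_gt_g1"):
        table[col.replace("p_", "q_", 1)], _ = bh_adjust(table[col], 0.05)
    return ScreenResult(table=table, n_g1=97, n_g2=9, group_order=("CLL", "NBC"))


class TestClassifySets:
    def test_rule_composition(self):
        sr = make_screen(
            {
                # IR up in group1, expression up -> (set-I, A)
                "t1": dict(p_ir_g1_gt_g2=1e-5, p_ir_g2_gt_g1=0.99,
                           p_expr_g1_gt_g2=1e-4, p_expr_g2_gt_g1=0.99,
                           p_expr_two_sided=2e-4),
                # IR up in group2, no expression difference -> (set-II, C)
                "t2": dict(p_ir_g1_gt_g2=0.99, p_ir_g2_gt_g1=1e-5,
                           p_expr_g1_gt_g2=0.6, p_expr_g2_gt_g1=0.45,
                           p_expr_two_sided=0.4),
                # no IR signal -> none
                "t3": dict(p_ir_g1_gt_g2=0.5, p_ir_g2_gt_g1=0.5,
                           p_expr_g1_gt_g2=0.01, p_expr_g2_gt_g1=0.99,
                           p_expr_two_sided=0.02),
                # IR up in group1 but no subset rule fits -> unassigned
                "t4": dict(p_ir_g1_gt_g2=1e-5, p_ir_g2_gt_g1=0.99,
                           p_expr_g1_gt_g2=0.2, p_expr_g2_gt_g1=0.8,
                           p_expr_two_sided=0.04),
            }
        )
        sa = classify_sets(sr)
        t = sa.table
        assert (t.loc["t1", ["ir_set", "expr_subset"]] == ["set-I", "A"]).all()
        assert (t.loc["t2", ["ir_set", "expr_subset"]] == ["set-II", "C"]).all()
        assert t.loc["t3", "ir_set"] == "none" and t.loc["t3", "expr_subset"] == ""
        assert t.loc["t4", "expr_subset"] == "unassigned"

    def test_raw_mode_uses_alpha(self):
        sr = make_screen(
            {
                f"t{i}": dict(p_ir_g1_gt_g2=1e-6, p_ir_g2_gt_g1=1.0,
                              p_expr_g1_gt_g2=0.04, p_expr_g2_gt_g1=0.96,
                              p_expr_two_sided=0.08)
                for i in range(3)
            }
            | {
                f"u{i}": dict(p_ir_g1_gt_g2=1e-6, p_ir_g2_gt_g1=1.0,
                              p_expr_g1_gt_g2=0.9, p_expr_g2_gt_g1=0.1,
                              p_expr_two_sided=0.2)
                for i in range(60)
            }
        )
        raw = classify_sets(sr, expr_mode="raw")
        assert (raw.table.loc["t0", ["ir_set", "expr_subset"]] == ["set-I", "A"]).all()

    def test_sets_disjoint_on_random_data(self, small_cohort):
        sr = run_screens(
            small_cohort.intronic.values, small_cohort.transcript.values,
            small_cohort.groups, group_order=("CLL", "NBC"),
        )
        sa = classify_sets(sr)
        assert set(sa.table["ir_set"]).issubset({"set-I", "set-II", "none"})
        # by construction a transcript has exactly one label; directional
        # q-values cannot both clear any level below 0.5
        both = (sa.table["q_ir_g1_gt_g2"] <= 0.25) & (sa.table["q_ir_g2_gt_g1"] <= 0.25)
        assert not both.any()

    def test_recovers_planted_labels(self, small_cohort):
        from irsplit.simulate import label_accuracy

        sr = run_screens(
            small_cohort.intronic.values, small_cohort.transcript.values,
            small_cohort.groups, group_order=("CLL", "NBC"),
        )
        sa = classify_sets(sr)
        assert label_accuracy(sa, small_cohort.truth) >= 0.90


# ---------- contingency ----------

class TestContingency:
    def assignment_from_counts(self, counts):
        rows = {}
        i = 0
        for ir_set, by_subset in counts.items():
            for subset, k in by_subset.items():
                for _ in range(k):
                    rows[f"t{i}"] = {"ir_set": ir_set, "expr_subset": subset}
                    i += 1
        from irsplit.classify import SetAssignment

        return SetAssignment(
            table=pd.DataFrame(rows).T, alpha=0.05, fdr_level=0.05,
            group_order=("CLL", "NBC"),
        )

    def test_strong_association(self):
        sa = self.assignment_from_counts(
            {"set-I": {"A": 10, "B": 1, "C": 2}, "set-II": {"A": 1, "B": 10, "C": 2}}
        )
        res = contingency(sa)
        assert res.odds_ratio == pytest.approx(100.0)
        assert res.fisher_p == pytest.approx(
            fisher_p_enumeration([[10, 1], [1, 10]]), rel=1e-9
        )
        assert res.table_2x3.loc["set-I"].sum() == 13  # marginal conservation

    def test_identical_rows_independent(self):
        sa = self.assignment_from_counts(
            {"set-I": {"A": 5, "B": 5, "C": 5}, "set-II": {"A": 5, "B": 5, "C": 5}}
        )
        res = contingency(sa)
        assert res.chi2_stat == pytest.approx(0.0)
        assert res.chi2_p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_haldane(self):
        sa = self.assignment_from_counts(
            {"set-I": {"A": 10, "B": 0, "C": 1}, "set-II": {"A": 2, "B": 5, "C": 1}}
        )
        res = contingency(sa)
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx((10.5 * 5.5) / (0.5 * 2.5))

    def test_reported_subset_percentages(self):
        # printed subset sizes of the high-IR set reproduce the printed split
        assert subset_percentages([10_436, 188, 1_345]) == [87, 2, 11]

    def test_half_up_rounding(self):
        assert subset_percentages([1, 7]) == [13, 88]  # 12.5 rounds up

    def test_fisher_matches_enumeration_on_small_tables(self):
        for table in itertools.product(range(4), repeat=4):
            a, b, c, d = table
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            t = [[a, b], [c, d]]
            _, p = stats.fisher_exact(t)
            assert p == pytest.approx(fisher_p_enumeration(t), rel=1e-9), t

    def test_sample_odds_ratio_proportional_rows(self):
        odds, corrected = sample_odds_ratio([[6, 9], [2, 3]])
        assert odds == pytest.approx(1.0) and not corrected
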
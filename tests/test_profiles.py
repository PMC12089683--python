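"""Cluster descriptives: state distributions, chi-square/ANOVA machinery."""

import numpy as np
import pytest
from scipy import stats

from careseq.profiles import (
    bonferroni,
    compare_categorical,
    compare_continuous,
    state_distribution,
    usage_curves,
)
from careseq.sequences import SequencePanel, StateSequence


class TestStateDistribution:
    def test_degenerate_cluster(self):
        seqs = [StateSequence(f"s{i}", (4,) * 5) for i in range(3)]
        dist = state_distribution({f"s{i}": 1 for i in range(3)}, SequencePanel(seqs))
        assert set(dist["state"]) == {4}
        assert np.all(dist["proportion"] == 1.0)

    def test_two_member_split(self):
        seqs = [StateSequence("a", (2, 2, 2, 2, 2)), StateSequence("b", (3, 3, 3, 3, 3))]
        dist = state_distribution({"a": 1, "b": 1}, SequencePanel(seqs))
        t1 = dist[dist["t"] == 1].set_index("state")["proportion"]
        assert t1[2] == 0.5 and t1[3] == 0.5
        use = usage_curves({"a": 1, "b": 1}, SequencePanel(seqs))
        t1u = use[use["t"] == 1].set_index("kind")["proportion"]
        assert t1u["therapy"] == 0.5 and t1u["counseling"] == 0.5 and t1u["medication"] == 0.0

    def test_proportions_sum_to_one(self, panel4):
        assignment = {i: 1 for i in panel4.ids}
        dist = state_distribution(assignment, panel4)
        sums = dist.groupby(["cluster", "t"])["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_marginal_usage_matches_generator_preferences(self, cohort4, panel4, truth4):
        """Usage curves reproduce each archetype's stationary usage rates."""
        assignment = {
            r.id: {"least_intervention": 1, "mostly_counseling": 2,
                   "mostly_medication": 3, "mixed_counseling_medication": 4}[label]
            for r, label in zip(cohort4.records, cohort4.true_labels)
            if r.id in panel4.demographics
        }
        use = usage_curves(assignment, panel4)
        med = use[(use["cluster"] == 3) & (use["kind"] == "medication")]["proportion"].mean()
        # archetype preference: ~0.94 medication (+ 0.022 C&M + 0.002 each T&M, T&C&M)
        assert med == pytest.approx(0.971, abs=0.05)
        couns = use[(use["cluster"] == 2) & (use["kind"] == "counseling")]["proportion"].mean()
        assert couns == pytest.approx(0.972, abs=0.05)


class TestChiSquare:
    def test_independence_gives_zero(self):
        values = {f"i{j}": ("x" if j % 2 else "y") for j in range(40)}
        assignment = {f"i{j}": (1 if j < 20 else 2) for j in range(40)}
        res = compare_categorical(values, assignment, variable="v")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association(self):
        values = {f"i{j}": ("x" if j < 20 else "y") for j in range(40)}
        assignment = {f"i{j}": (1 if j < 20 else 2) for j in range(40)}
        res = compare_categorical(values, assignment)
        assert res.statistic == pytest.approx(40.0, abs=1e-12)
        assert res.effect_size == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_reference(self, rng):
        for _ in range(50):
            r, c = int(rng.integers(2, 5)), int(rng.integers(2, 4))
            table = rng.integers(1, 30, size=(r, c))
            values, assignment = {}, {}
            idx = 0
            for i in range(r):
                for j in range(c):
                    for _k in range(table[i, j]):
                        values[f"p{idx}"] = f"cat{j}"
                        assignment[f"p{idx}"] = i + 1
                        idx += 1
            res = compare_categorical(values, assignment)
            ref = stats.chi2_contingency(table, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_missing_values_excluded(self):
        values = {"a": "x", "b": None, "c": "y", "d": "x", "e": "y", "f": "x"}
        assignment = {k: (1 if k in "abc" else 2) for k in values}
        assert compare_categorical(values, assignment).n_used == 5


class TestAnova:
    def test_identical_groups_zero_f(self):
        values = {f"i{j}": float(j % 3) for j in range(30)}
        assignment = {f"i{j}": (1 if j < 15 else 2) for j in range(30)}
        # same multiset of values in both groups -> means equal -> F = 0
        res = compare_continuous(values, assignment)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        values = dict(a=1.0, b=2.0, c=3.0, d=4.0, e=5.0, f=6.0)
        assignment = dict(a=1, b=1, c=1, d=2, e=2, f=2)
        res = compare_continuous(values, assignment)
        assert res.statistic == pytest.approx(13.5, abs=1e-12)  # SSB=13.5, SSW/df=1
        assert res.effect_size == pytest.approx(13.5 / 17.5, abs=1e-12)
        assert res.df == (1, 4)
        assert res.posthoc[0][2] == "2 > 1"

    def test_matches_scipy_reference(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 5))
            samples = [rng.normal(rng.normal(), 1, size=rng.integers(3, 15)) for _ in range(k)]
            values, assignment = {}, {}
            idx = 0
            for g, s in enumerate(samples, start=1):
                for v in s:
                    values[f"p{idx}"] = float(v)
                    assignment[f"p{idx}"] = g
                    idx += 1
            res = compare_continuous(values, assignment)
            ref = stats.f_oneway(*samples)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_variance_flagged(self):
        values = {k: 1.0 for k in "abcdef"}
        assignment = {k: (1 if k in "abc" else 2) for k in "abcdef"}
        res = compare_continuous(values, assignment)
        assert "zero-within-variance" in res.flags


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni([0.01], 6) == [0.06]
        assert bonferroni([0.5], 6) == [1.0]
        assert bonferroni([0.04], 1) == [0.04]

    def test_order_preserving(self):
        adj = bonferroni([0.001, 0.01, 0.04], 6)
        assert adj == sorted(adj)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 3)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestEffectSizeInvariance:
    def test_relabeling_clusters_leaves_v_and_eta2(self, rng):
        values_cat = {f"i{j}": f"c{rng.integers(0, 3)}" for j in range(60)}
        values_num = {f"i{j}": float(rng.normal()) for j in range(60)}
        assignment = {f"i{j}": int(rng.integers(1, 4)) for j in range(60)}
        relabel = {1: 3, 2: 1, 3: 2}
        swapped = {i: relabel[g] for i, g in assignment.items()}
        a = compare_categorical(values_cat, assignment)
        b = compare_categorical(values_cat, swapped)
        assert a.effect_size == pytest.approx(b.effect_size, abs=1e-12)
        c = compare_continuous(values_num, assignment)
        d = compare_continuous(values_num, swapped)
        assert c.effect_size == pytest.approx(d.effect_size, abs=1e-12)
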
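"""Partition correspondence criteria and sensitivity re-analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from careseq.clustering import cut_clusters, ward_linkage
from careseq.cohort import default_config, generate_cohort
from careseq.crossval import (
    MatchCriteria,
    SensitivityError,
    compare_solutions,
    match_criteria,
    modal_profile,
    participant_overlap,
    run_sensitivity,
)
from careseq.dissimilarity import distance_matrix
from careseq.sequences import SequencePanel, StateSequence, build_panel, fill_intermittent


def assign_from_sets(*sets):
    out = {}
    for label, ids in enumerate(sets, start=1):
        for i in ids:
            out[str(i)] = label
    return out


class TestParticipantOverlap:
    def test_half_overlap(self):
        a = assign_from_sets({1, 2, 3, 4}, {5, 6, 7, 8})
        b = assign_from_sets({3, 4, 5, 6}, {1, 2, 7, 8})
        t = participant_overlap(a, b)
        assert t.counts.loc[1, 1] == 2
        assert t.pct_a_in_b.loc[1, 1] == 50.0
        assert t.pct_b_in_a.loc[1, 1] == 50.0

    def test_reported_percentage_arithmetic(self):
        # a 51-member cluster sharing 39 ids with a 95-member subgroup
        cluster = assign_from_sets(range(51), range(51, 146))
        subgroup = assign_from_sets(set(range(39)) | set(range(51, 107)), set(range(39, 51)) | set(range(107, 146)))
        t = participant_overlap(cluster, subgroup)
        assert t.counts.loc[1, 1] == 39
        assert round(float(t.pct_a_in_b.loc[1, 1]), 1) == 76.5
        assert round(float(t.pct_b_in_a.loc[1, 1]), 1) == 41.1

    def test_identical_partitions_diagonal(self):
        a = assign_from_sets({1, 2}, {3, 4, 5})
        t = participant_overlap(a, a)
        assert all(t.pct_a_in_b.loc[c, c] == 100.0 for c in (1, 2))

    def test_margins_reproduce_sizes(self, panel4, D4):
        sol4 = cut_clusters(ward_linkage(D4), 4)
        sol5 = cut_clusters(ward_linkage(D4), 5)
        t = participant_overlap(sol4.assignment, sol5.assignment)
        assert t.a_sizes.to_dict() == sol4.sizes
        assert t.b_sizes.to_dict() == sol5.sizes

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="symmetric difference"):
            participant_overlap({"a": 1}, {"b": 1})


class TestModalProfile:
    def test_uniform_medication_group(self):
        seqs = [StateSequence(f"s{i}", (4,) * 5) for i in range(3)]
        prof = modal_profile({f"s{i}": 1 for i in range(3)}, SequencePanel(seqs))
        assert prof.modal_state[1] == [4] * 5
        assert prof.majority_use[1]["medication"] == [True] * 5
        assert prof.majority_use[1]["therapy"] == [False] * 5
        assert prof.majority_use[1]["counseling"] == [False] * 5

    def test_modal_tie_breaks_to_lower_code(self):
        seqs = [
            StateSequence("a", (1, 1, 1, 1, 1)),
            StateSequence("b", (1, 1, 1, 1, 1)),
            StateSequence("c", (3, 3, 3, 3, 3)),
        ]
        prof = modal_profile({"a": 1, "b": 1, "c": 1}, SequencePanel(seqs))
        assert prof.modal_state[1][0] == 1
        assert prof.majority_use[1]["counseling"][0] is False  # 1/3 < 0.5


class TestMatchCriteria:
    def _profile(self, states, use):
        return (states, {k: use for k in ("therapy", "counseling", "medication")})

    def test_identical_groups_pass_all(self):
        p = self._profile([3] * 7, [True] * 7)
        dems = [{"age": 40 + i, "sex": "female"} for i in range(10)]
        entry = match_criteria(p, p, 100.0, dems, dems)
        assert entry.matched

    def test_strict_75_percent_threshold(self):
        p = self._profile([3] * 7, [True] * 7)
        dems = [{"age": 40.0 + i} for i in range(10)]
        entry = match_criteria(p, p, 74.9, dems, dems)
        assert not entry.criterion3_pass and not entry.matched
        assert match_criteria(p, p, 75.0, dems, dems).criterion3_pass

    def test_planted_archetype_pair_matches(self, panel4, truth4, D4):
        sol = cut_clusters(ward_linkage(D4), 4)
        # the biggest planted archetype and its recovered cluster
        gb = {i: 1 if truth4[i] == "least_intervention" else 2 for i in panel4.ids}
        prof_a = modal_profile(sol.assignment, panel4)
        prof_b = modal_profile(gb, panel4)
        overlap = participant_overlap(sol.assignment, gb)
        c = int(overlap.counts[1].idxmax())  # cluster holding most archetype members
        dems_a = [panel4.demographics[i] for i, cc in sol.assignment.items() if cc == c]
        dems_b = [panel4.demographics[i] for i, gg in gb.items() if gg == 1]
        entry = match_criteria(
            (prof_a.modal_state[c], prof_a.majority_use[c]),
            (prof_b.modal_state[1], prof_b.majority_use[1]),
            float(overlap.pct_a_in_b.loc[c, 1]),
            dems_a, dems_b,
        )
        assert entry.matched


class TestCompareSolutions:
    def test_identical_partitions(self):
        a = assign_from_sets({1, 2, 3}, {4, 5, 6})
        cmp = compare_solutions(a, a)
        assert cmp.ari == 1.0 and all(v == 1.0 for v in cmp.best_jaccard.values())

    def test_single_cluster_vs_split_has_zero_ari(self):
        a = {str(i): 1 for i in range(10)}
        b = assign_from_sets(range(5), range(5, 10))
        assert compare_solutions(a, b).ari == 0.0

    @given(st.permutations([1, 2, 3]))
    @settings(max_examples=10, deadline=None)
    def test_label_permutation_invariance(self, perm):
        a = assign_from_sets({1, 2, 3}, {4, 5}, {6, 7, 8})
        b = {i: perm[c - 1] for i, c in a.items()}
        cmp = compare_solutions(a, b)
        assert cmp.ari == 1.0

    def test_symmetry(self):
        a = assign_from_sets({1, 2, 3, 4}, {5, 6, 7, 8})
        b = assign_from_sets({1, 2, 5, 6}, {3, 4, 7, 8})
        assert compare_solutions(a, b).ari == pytest.approx(compare_solutions(b, a).ari)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            compare_solutions({"a": 1}, {"b": 1})


@pytest.fixture(scope="module")
def stationary_panel():
    cfg = default_config(n=150, seed=13, include_heterogeneous=False,
                         intermittent_missing_rate=0.0)
    cfg.wave_length_probs = {7: 1.0}
    cohort = generate_cohort(cfg)
    return build_panel([fill_intermittent(r) for r in cohort.records])


class TestRunSensitivity:
    def test_covid_drop_preserves_stationary_structure(self, stationary_panel):
        D = distance_matrix(stationary_panel)
        sol = cut_clusters(ward_linkage(D), 4)
        rep = run_sensitivity(stationary_panel, sol, "covid_drop", k_range=range(2, 7))
        assert rep.comparison.ari >= 0.8
        assert all(s.length == 5 for s in rep.panel.sequences)

    def test_missing_state_identical_without_missingness(self, stationary_panel):
        D = distance_matrix(stationary_panel)
        sol = cut_clusters(ward_linkage(D), 4)
        rep = run_sensitivity(stationary_panel, sol, "missing_state", k_range=range(2, 7))
        assert rep.comparison.ari == 1.0

    def test_unknown_mode_rejected(self, stationary_panel):
        sol = cut_clusters(ward_linkage(distance_matrix(stationary_panel)), 2)
        with pytest.raises(ValueError, match="mode"):
            run_sensitivity(stationary_panel, sol, "leave_one_out")

    def test_abort_when_too_few_remain(self):
        # everyone observed 2016-2020 only: dropping 2020 leaves 4 waves
        cfg = default_config(n=40, seed=3, include_heterogeneous=False,
                             intermittent_missing_rate=0.0)
        cfg.wave_length_probs = {5: 1.0}
        cohort = generate_cohort(cfg)
        from careseq.sequences import IndividualRecord
        from dataclasses import replace

        recs = [replace(r, first_year=2016) for r in cohort.records]
        panel = build_panel(recs)
        sol = cut_clusters(ward_linkage(distance_matrix(panel)), 2)
        with pytest.raises(SensitivityError):
            run_sensitivity(panel, sol, "covid_drop")
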
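"""Correspondence between clusterings and sensitivity re-analyses.

Two partitions of the cohort — the sequence-analysis clusters and the
trajectory-model subgroups — are compared with a cross-tabulation and four
explicit correspondence criteria: (1) similar modal trajectory, (2) same
group-majority usage of each intervention kind on at least half the years,
(3) at least 75% of the cluster's members in the subgroup, and (4) a shared
demographic profile.  The same machinery compares the original clustering
to the two sensitivity re-runs (pandemic years removed; missing waves coded
as an explicit state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import clustering as _cl
from .dissimilarity import distance_matrix
from .sequences import SequencePanel, decode_state, drop_waves

__all__ = [
    "OverlapTable",
    "ModalProfile",
    "MatchCriteria",
    "MatchReportEntry",
    "participant_overlap",
    "modal_profile",
    "match_criteria",
    "compare_solutions",
    "run_sensitivity",
    "SensitivityError",
]


class SensitivityError(RuntimeError):
    """A sensitivity rerun left too few individuals to cluster meaningfully."""


@dataclass
class OverlapTable:
    """Cross-tabulation of two partitions with row/column percentages."""

    counts: pd.DataFrame  # rows: partition A groups; columns: partition B groups
    pct_a_in_b: pd.DataFrame  # shared / |A group| * 100
    pct_b_in_a: pd.DataFrame  # shared / |B group| * 100

    @property
    def a_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def b_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def participant_overlap(assignA: Mapping[str, int], assignB: Mapping[str, int]) -> OverlapTable:
    """Exact cross-tabulation of two assignments over the same id universe."""
    if set(assignA) != set(assignB):
        diff = sorted(set(assignA) ^ set(assignB))
        raise ValueError(f"id universes differ; symmetric difference: {diff}")
    ids = sorted(assignA)
    a = pd.Series([assignA[i] for i in ids], name="a")
    b = pd.Series([assignB[i] for i in ids], name="b")
    counts = pd.crosstab(a, b)
    pct_a = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct_b = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return OverlapTable(counts=counts, pct_a_in_b=pct_a, pct_b_in_a=pct_b)


@dataclass
class ModalProfile:
    """Per-group, per-time-point modal state and majority usage flags.

    ``modal_state[g]`` is a list over T1..TL (None where no member is
    observed); ``majority_use[g][kind]`` is the per-time-point flag that at
    least 50% of the observed members used that intervention kind.
    """

    modal_state: dict[int, list[Optional[int]]]
    majority_use: dict[int, dict[str, list[Optional[bool]]]]
    n_observed: dict[int, list[int]]

    def horizon(self, g: int) -> int:
        return len(self.modal_state[g])


_KINDS = ("therapy", "counseling", "medication")


def modal_profile(assignment: Mapping[str, int], panel: SequencePanel) -> ModalProfile:
    """Modal state and majority intervention use per group and time point.

    Frequencies at each time point are taken over the members still observed
    there; modal-state ties break toward the lower state code.  Waves coded
    as missing (state 9) are not counted as observations.
    """
    by_group: dict[int, list] = {}
    for s in panel.sequences:
        g = assignment.get(s.id)
        if g is None:
            raise ValueError(f"no assignment for id {s.id!r}")
        by_group.setdefault(int(g), []).append(s)
    modal: dict[int, list[Optional[int]]] = {}
    major: dict[int, dict[str, list[Optional[bool]]]] = {}
    nobs: dict[int, list[int]] = {}
    for g, seqs in sorted(by_group.items()):
        T = max(s.length for s in seqs)
        modal[g] = []
        major[g] = {k: [] for k in _KINDS}
        nobs[g] = []
        for t in range(T):
            states = [s.states[t] for s in seqs if t < s.length and s.states[t] != 9]
            nobs[g].append(len(states))
            if not states:
                modal[g].append(None)
                for k in _KINDS:
                    major[g][k].append(None)
                continue
            vals, cnts = np.unique(states, return_counts=True)
            modal[g].append(int(vals[np.argmax(cnts)]))  # np.unique sorts -> lower code on ties
            triples = np.array([decode_state(c) for c in states], dtype=float)
            for ki, k in enumerate(_KINDS):
                major[g][k].append(bool(triples[:, ki].mean() >= 0.5))
    return ModalProfile(modal_state=modal, majority_use=major, n_observed=nobs)


@dataclass(frozen=True)
class MatchCriteria:
    """Thresholds for the four correspondence criteria."""

    modal_agreement: float = 0.5  # criterion 1: fraction of time points
    overlap_pct: float = 75.0  # criterion 3
    smd_threshold: float = 0.5  # criterion 4, continuous covariates
    prop_threshold: float = 0.2  # criterion 4, categorical covariates


@dataclass
class MatchReportEntry:
    """Pass/fail of the four criteria for one (cluster, subgroup) pair."""

    cluster: int
    subgroup: int
    criterion1_pass: bool
    criterion2_pass: bool
    criterion3_pass: bool
    criterion4_pass: bool
    modal_agreement: float
    usage_agreement_years: dict[str, int]
    pct_cluster_in_subgroup: float
    demographic_differences: dict[str, float]

    @property
    def matched(self) -> bool:
        return (
            self.criterion1_pass
            and self.criterion2_pass
            and self.criterion3_pass
            and self.criterion4_pass
        )


_CONTINUOUS = ("age", "age_dx")
_BINARY = ("partner", "employment", "psychiatric")
_CATEGORICAL = ("sex", "education")


def _demographic_differences(
    demA: Sequence[Mapping[str, object]], demB: Sequence[Mapping[str, object]]
) -> dict[str, float]:
    """Standardized mean differences (continuous) / max proportion gaps (categorical)."""
    out: dict[str, float] = {}

    def col(dems, v):
        return [d.get(v) for d in dems if d.get(v) is not None]

    for v in _CONTINUOUS:
        xa, xb = col(demA, v), col(demB, v)
        if len(xa) > 1 and len(xb) > 1:
            xa, xb = np.asarray(xa, float), np.asarray(xb, float)
            sp = np.sqrt((xa.var(ddof=1) + xb.var(ddof=1)) / 2.0)
            out[v] = abs(xa.mean() - xb.mean()) / sp if sp > 0 else 0.0
    for v in _BINARY + _CATEGORICAL:
        xa, xb = col(demA, v), col(demB, v)
        if xa and xb:
            cats = set(xa) | set(xb)
            gap = max(
                abs(xa.count(c) / len(xa) - xb.count(c) / len(xb)) for c in cats
            )
            out[v] = gap
    return out


def match_criteria(
    cluster_profile: tuple[list[Optional[int]], dict[str, list[Optional[bool]]]],
    subgroup_profile: tuple[list[Optional[int]], dict[str, list[Optional[bool]]]],
    pct_cluster_in_subgroup: float,
    demographicsA: Sequence[Mapping[str, object]],
    demographicsB: Sequence[Mapping[str, object]],
    thresholds: MatchCriteria = MatchCriteria(),
    cluster: int = 0,
    subgroup: int = 0,
) -> MatchReportEntry:
    """Evaluate the four correspondence criteria for one pair of groups.

    Unequal time horizons are compared over the shorter one.  Criterion 2
    requires, for each intervention kind, agreement of the group-majority
    usage flag on at least ceil(T/2) of the T compared years.
    """
    modalA, useA = cluster_profile
    modalB, useB = subgroup_profile
    T = min(len(modalA), len(modalB))
    comparable = [t for t in range(T) if modalA[t] is not None and modalB[t] is not None]
    agree = sum(1 for t in comparable if modalA[t] == modalB[t])
    frac = agree / len(comparable) if comparable else 0.0
    c1 = frac >= thresholds.modal_agreement

    usage_years: dict[str, int] = {}
    c2 = True
    for k in _KINDS:
        ok = sum(
            1
            for t in range(T)
            if useA[k][t] is not None and useB[k][t] is not None and useA[k][t] == useB[k][t]
        )
        usage_years[k] = ok
        if ok < ceil(T / 2):
            c2 = False

    c3 = pct_cluster_in_subgroup >= thresholds.overlap_pct

    diffs = _demographic_differences(demographicsA, demographicsB)
    c4 = all(
        (diffs[v] < thresholds.smd_threshold if v in _CONTINUOUS else diffs[v] < thresholds.prop_threshold)
        for v in diffs
    )
    return MatchReportEntry(
        cluster=cluster,
        subgroup=subgroup,
        criterion1_pass=c1,
        criterion2_pass=c2,
        criterion3_pass=c3,
        criterion4_pass=c4,
        modal_agreement=frac,
        usage_agreement_years=usage_years,
        pct_cluster_in_subgroup=float(pct_cluster_in_subgroup),
        demographic_differences=diffs,
    )


@dataclass
class SolutionComparison:
    n_common: int
    crosstab: pd.DataFrame
    ari: float
    best_jaccard: dict[int, float]  # per cluster of A


def compare_solutions(assignA: Mapping[str, int], assignB: Mapping[str, int]) -> SolutionComparison:
    """Cross-tabulation, adjusted Rand index, and per-cluster best Jaccard.

    Computed over the intersection of the two id universes (its size is
    reported); raises on an empty intersection.
    """
    common = sorted(set(assignA) & set(assignB))
    if not common:
        raise ValueError("no common ids between the two assignments")
    a = np.array([assignA[i] for i in common])
    b = np.array([assignB[i] for i in common])
    ct = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    ari = float(adjusted_rand_score(a, b))
    best: dict[int, float] = {}
    for c in np.unique(a):
        mask_c = a == c
        best[int(c)] = max(
            float(np.sum(mask_c & (b == r)) / np.sum(mask_c | (b == r))) for r in np.unique(b)
        )
    return SolutionComparison(n_common=len(common), crosstab=ct, ari=ari, best_jaccard=best)


COVID_YEARS = frozenset({2020, 2021})


@dataclass
class SensitivityReport:
    mode: str
    panel: SequencePanel
    report: _cl.SolutionReport
    solution: _cl.ClusterSolution
    comparison: SolutionComparison
    dropped: list[tuple[str, str]]


def run_sensitivity(
    panel: SequencePanel,
    original: _cl.ClusterSolution,
    mode: str,
    *,
    norm: str = "gmean",
    dialect: str = "ward_d2",
    k_range: Sequence[int] = range(2, 9),
    min_prop: float = 0.10,
) -> SensitivityReport:
    """Re-run distance + clustering under a perturbed design and compare.

    ``covid_drop`` removes calendar years 2020-2021 before eligibility and
    alignment; ``missing_state`` rebuilds the panel on the 9-state alphabet
    so unfillable missing waves become an ordinary symbol.  The rerun is cut
    at the original solution's k and compared by ARI/Jaccard; the full
    quality report over ``k_range`` is attached.
    """
    if panel.records is None:
        raise ValueError("panel does not retain its source records")
    if mode == "covid_drop":
        new_panel = drop_waves(panel, set(COVID_YEARS))
    elif mode == "missing_state":
        from .sequences import build_panel

        new_panel = build_panel(panel.records, alphabet="state9")
    else:
        raise ValueError(f"unknown sensitivity mode {mode!r}")
    n = new_panel.n
    if n < 2 * ceil(min_prop * max(panel.n, 1)):
        raise SensitivityError(
            f"{mode}: only {n} of {panel.n} individuals remain eligible; aborting"
        )
    D = distance_matrix(new_panel, norm)
    dend = _cl.ward_linkage(D, dialect)
    report = _cl.select_solution(D, k_range=k_range, min_prop=min_prop, dialect=dialect, dendrogram=dend)
    k = original.k
    solution = report.solutions.get(k) or _cl.cut_clusters(dend, k)
    comparison = compare_solutions(original.assignment, solution.assignment)
    return SensitivityReport(
        mode=mode,
        panel=new_panel,
        report=report,
        solution=solution,
        comparison=comparison,
        dropped=list(new_panel.dropped),
    )
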
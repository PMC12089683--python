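"""Cluster descriptives: state distributions and demographic comparisons.

State distributions per cluster and time point back the state-index and
pie-chart style summaries.  Demographic comparisons use Pearson chi-square
tests (categorical) or one-way ANOVA (continuous) with Cramer's V / eta^2
effect sizes and Bonferroni-corrected pairwise post hocs; all analyses are
complete-case per variable, with the denominator reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequences import SequencePanel, decode_state

__all__ = [
    "ComparisonResult",
    "state_distribution",
    "usage_curves",
    "compare_categorical",
    "compare_continuous",
    "bonferroni",
    "profile_table",
]


def state_distribution(assignment: Mapping[str, int], panel: SequencePanel) -> pd.DataFrame:
    """Tidy table of state proportions per (cluster, time point).

    Proportions are over the members observed at that time point and sum to
    one within each (cluster, t) cell group.
    """
    rows = []
    by_group: dict[int, list] = {}
    for s in panel.sequences:
        by_group.setdefault(int(assignment[s.id]), []).append(s)
    for g, seqs in sorted(by_group.items()):
        T = max(s.length for s in seqs)
        for t in range(T):
            states = [s.states[t] for s in seqs if t < s.length]
            if not states:
                continue
            vals, cnts = np.unique(states, return_counts=True)
            for v, c in zip(vals, cnts):
                rows.append(
                    dict(cluster=g, t=t + 1, state=int(v), proportion=c / len(states),
                         n_observed=len(states))
                )
    return pd.DataFrame(rows)


def usage_curves(assignment: Mapping[str, int], panel: SequencePanel) -> pd.DataFrame:
    """Per-cluster marginal usage proportion of each intervention kind over time."""
    dist = state_distribution(assignment, panel)
    rows = []
    for (g, t), sub in dist.groupby(["cluster", "t"]):
        use = {"therapy": 0.0, "counseling": 0.0, "medication": 0.0}
        denom = 0.0
        for _, r in sub.iterrows():
            triple = decode_state(int(r["state"]))
            if triple[0] is None:
                continue  # missing state carries no usage information
            denom += r["proportion"]
            for k, v in zip(use, triple):
                use[k] += r["proportion"] * v
        for k in use:
            rows.append(dict(cluster=g, t=t, kind=k,
                             proportion=use[k] / denom if denom > 0 else np.nan))
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """One demographic comparison across clusters."""

    variable: str
    test: str  # "chi_square" | "anova"
    statistic: float
    df: tuple
    p_value: float
    effect_size: float  # Cramer's V or eta^2
    n_used: int
    posthoc: list[tuple[tuple[int, int], float, str]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def posthoc_summary(self, alpha: float = 0.05) -> str:
        parts = [f"{d}" for (_pair, p, d) in self.posthoc if p < alpha and d]
        return "; ".join(parts)


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment with an explicit family size: min(1, p * m)."""
    ps = list(p_values)
    if m < len(ps):
        raise ValueError("family size m must be >= number of p-values")
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in ps]


def _chi2_stat(table: np.ndarray) -> tuple[float, int, np.ndarray]:
    """Pearson chi-square statistic, df and expected counts (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    n = table.sum()
    expected = rowsum @ colsum / n
    stat = float(np.sum((table - expected) ** 2 / expected))
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df, expected


def compare_categorical(
    values: Mapping[str, object],
    assignment: Mapping[str, int],
    clusters_subset: Optional[Sequence[int]] = None,
    variable: str = "",
) -> ComparisonResult:
    """Pearson chi-square over the cluster x category table, with Cramer's V.

    Pairwise 2-group chi-square post hocs are Bonferroni-adjusted over all
    pairs in the subset.  Complete cases only; expected counts below 1 flag
    the result but do not suppress it.
    """
    data = {
        i: (assignment[i], values[i])
        for i in assignment
        if clusters_subset is None or assignment[i] in clusters_subset
    }
    data = {i: (g, v) for i, (g, v) in data.items() if v is not None and v == v}
    groups = sorted({g for g, _ in data.values()})
    cats = sorted({v for _, v in data.values()}, key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    table = np.zeros((len(groups), len(cats)))
    for g, v in data.values():
        table[groups.index(g), cats.index(v)] += 1
    stat, df, expected = _chi2_stat(table)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    n = table.sum()
    r, c = table.shape
    v_cramer = float(np.sqrt(stat / (n * (min(r, c) - 1)))) if min(r, c) > 1 else 0.0
    flags = ["low-expected-count"] if np.any(expected < 1) else []

    pairs = list(combinations(groups, 2))
    posthoc = []
    raw = []
    for a, b in pairs:
        sub = table[[groups.index(a), groups.index(b)], :]
        sub = sub[:, sub.sum(axis=0) > 0]
        if sub.shape[1] < 2:
            raw.append((1.0, ""))
            continue
        s, d, _ = _chi2_stat(sub)
        raw.append((float(stats.chi2.sf(s, d)), f"{a} != {b}"))
    adj = bonferroni([p_ for p_, _ in raw], len(pairs))
    for (pair, (p_raw, direction), p_adj) in zip(pairs, raw, adj):
        posthoc.append((pair, p_adj, direction if p_adj < 0.05 else ""))
    return ComparisonResult(
        variable=variable, test="chi_square", statistic=stat, df=(df,), p_value=p,
        effect_size=v_cramer, n_used=int(n), posthoc=posthoc, flags=flags,
    )


def compare_continuous(
    values: Mapping[str, float],
    assignment: Mapping[str, int],
    clusters_subset: Optional[Sequence[int]] = None,
    variable: str = "",
) -> ComparisonResult:
    """One-way fixed-effects ANOVA with eta^2 and pooled-t Bonferroni post hocs.

    Directions are reported as "a > b" for pairs significant after
    adjustment.  Zero within-group variance everywhere leaves F undefined
    (flagged, statistic NaN).
    """
    data: dict[int, list[float]] = {}
    for i, g in assignment.items():
        if clusters_subset is not None and g not in clusters_subset:
            continue
        v = values.get(i)
        if v is None or v != v:
            continue
        data.setdefault(int(g), []).append(float(v))
    groups = sorted(data)
    if len(groups) < 2 or any(len(data[g]) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 complete cases each")
    samples = [np.asarray(data[g]) for g in groups]
    n = sum(len(s) for s in samples)
    grand = np.concatenate(samples).mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    dfb, dfw = len(groups) - 1, n - len(groups)
    flags: list[str] = []
    if ssw == 0:
        flags.append("zero-within-variance")
        F, p = float("nan"), float("nan")
    else:
        F = float((ssb / dfb) / (ssw / dfw))
        p = float(stats.f.sf(F, dfb, dfw))
    sst = ssb + ssw
    eta2 = float(ssb / sst) if sst > 0 else 0.0

    pairs = list(combinations(groups, 2))
    raw, dirs = [], []
    for a, b in pairs:
        xa, xb = np.asarray(data[a]), np.asarray(data[b])
        sp2 = (((xa - xa.mean()) ** 2).sum() + ((xb - xb.mean()) ** 2).sum()) / (
            len(xa) + len(xb) - 2
        )
        if sp2 == 0:
            raw.append(1.0)
            dirs.append("")
            continue
        t = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / len(xa) + 1 / len(xb)))
        raw.append(float(2 * stats.t.sf(abs(t), len(xa) + len(xb) - 2)))
        dirs.append(f"{a} > {b}" if xa.mean() > xb.mean() else f"{b} > {a}")
    adj = bonferroni(raw, len(pairs))
    posthoc = [
        (pair, p_adj, d if p_adj < 0.05 else "") for pair, p_adj, d in zip(pairs, adj, dirs)
    ]
    return ComparisonResult(
        variable=variable, test="anova", statistic=F, df=(dfb, dfw), p_value=p,
        effect_size=eta2, n_used=int(n), posthoc=posthoc, flags=flags,
    )


_CONTINUOUS_VARS = ("age", "age_dx")
_CATEGORICAL_VARS = ("sex", "education", "partner", "employment", "psychiatric")


def profile_table(
    panel: SequencePanel,
    assignment: Mapping[str, int],
    clusters_subset: Optional[Sequence[int]] = None,
    sex_levels: int = 2,
) -> pd.DataFrame:
    """Demographic comparison table across clusters (one row per variable).

    ``sex_levels=2`` restricts the sex comparison to female/male; other
    responses are kept in the descriptives but excluded from the test, since
    tiny cells make a 3-level test degenerate.
    """
    rows = []
    dem = panel.demographics
    for var in _CONTINUOUS_VARS + _CATEGORICAL_VARS:
        values = {i: d.get(var) for i, d in dem.items()}
        if var == "sex" and sex_levels == 2:
            values = {i: v for i, v in values.items() if v in ("female", "male", None)}
        assign_sub = {i: assignment[i] for i in values if i in assignment}
        try:
            if var in _CONTINUOUS_VARS:
                res = compare_continuous(values, assign_sub, clusters_subset, variable=var)
            else:
                res = compare_categorical(values, assign_sub, clusters_subset, variable=var)
        except ValueError:
            continue
        rows.append(
            dict(variable=var, test=res.test, statistic=res.statistic,
                 df="/".join(str(d) for d in res.df), p=res.p_value,
                 effect_size=res.effect_size, n_used=res.n_used,
                 posthoc=res.posthoc_summary(), flags=";".join(res.flags))
        )
    return pd.DataFrame(rows)
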
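"""End-to-end pipeline: simulate/ingest -> sequences -> distances -> clusters
-> stability -> trajectory-model cross-validation -> sensitivity -> profiles.

Every stage writes plain-CSV artifacts into a run directory, together with a
manifest recording the configuration hash, seed and library versions, so a
run can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    ClusterSolution,
    bootstrap_jaccard,
    cut_clusters,
    interpret_quality,
    select_solution,
    ward_linkage,
)
from .cohort import default_config, export_cohort, generate_cohort
from .crossval import (
    MatchCriteria,
    match_criteria,
    modal_profile,
    participant_overlap,
    run_sensitivity,
)
from .dissimilarity import distance_matrix
from .gbmt import GbmtSpec, posterior_assign, select_gbmt
from .io import read_records, write_matrix, write_panel
from .profiles import profile_table, state_distribution, usage_curves
from .sequences import FillRule, build_panel, fill_intermittent

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("careseq")


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run (YAML-serializable)."""

    # input: either a CSV path or a synthetic cohort
    input_path: Optional[str] = None
    input_format: str = "wide"
    synth_n: int = 445
    synth_heterogeneous: bool = True
    synth_intermittent_rate: float = 0.02
    synth_attrition_hazard: float = 0.0
    # sequence construction
    alphabet: str = "state8"
    fill_tie: str = "carry_forward"
    # distances / clustering
    norm: str = "gmean"
    dialect: str = "ward_d2"
    k_min: int = 2
    k_max: int = 8
    min_prop: float = 0.10
    chosen_k: Optional[int] = None  # default: top-ranked admissible
    bootstrap_B: int = 100
    # trajectory model
    gbmt_degree: int = 2
    gbmt_starts: int = 5
    gbmt_max_iter: int = 300
    gbmt_tol: float = 1e-6
    gbmt_k_range: Optional[list[int]] = None  # default: same as k range
    # sensitivity
    sensitivity: list[str] = field(default_factory=lambda: ["covid_drop", "missing_state"])
    # run controls
    outdir: str = "careseq_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.alphabet not in ("state8", "state9"):
            raise ValueError("alphabet must be state8 or state9")
        if not (0 < self.min_prop < 1):
            raise ValueError("min_prop must be in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.bootstrap_B < 0:
            raise ValueError("bootstrap_B must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    panel: object
    solution: ClusterSolution
    report: object
    gbmt_fit: object
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all analysis stages and write every artifact under ``outdir``."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    k_range = range(config.k_min, config.k_max + 1)

    # --- input -------------------------------------------------------------
    if config.input_path:
        log.info("Step 1: reading records from %s (%s)", config.input_path, config.input_format)
        records = read_records(config.input_path, config.input_format)
    else:
        log.info("Step 1: simulating synthetic cohort (n=%d, seed=%d)", config.synth_n, config.seed)
        cohort = generate_cohort(
            default_config(
                n=config.synth_n,
                seed=config.seed,
                include_heterogeneous=config.synth_heterogeneous,
                intermittent_missing_rate=config.synth_intermittent_rate,
                attrition_hazard=config.synth_attrition_hazard,
            )
        )
        export_cohort(cohort, out / "cohort_wide.csv", format="wide")
        pd.DataFrame({"id": [r.id for r in cohort.records], "archetype": cohort.true_labels}).to_csv(
            out / "cohort_truth.csv", index=False
        )
        records = cohort.records

    # --- Steps 1-2: fill + panel ------------------------------------------
    log.info("Step 1: filling intermittent gaps; Step 2: building left-aligned panel")
    rule = FillRule(tie=config.fill_tie)
    filled = [fill_intermittent(r, rule) for r in records]
    panel = build_panel(filled, alphabet=config.alphabet)
    write_panel(panel, out / "panel.csv")
    if panel.dropped:
        pd.DataFrame(panel.dropped, columns=["id", "reason"]).to_csv(out / "excluded.csv", index=False)

    # --- Step 3: dissimilarities ------------------------------------------
    log.info("Step 3: LCS dissimilarity matrix (norm=%s) over %d sequences", config.norm, panel.n)
    D = distance_matrix(panel, config.norm)
    write_matrix(D, out / "distances.csv")

    # --- Step 4: clustering ------------------------------------------------
    log.info("Step 4: Ward clustering (%s), k in %s", config.dialect, list(k_range))
    dend = ward_linkage(D, config.dialect)
    (out / "dendrogram.txt").write_text(dend.to_newick() + "\n")
    report = select_solution(D, k_range=k_range, min_prop=config.min_prop, dendrogram=dend)
    k = config.chosen_k or (report.ranked_admissible[0] if report.ranked_admissible else config.k_min)
    solution = report.solutions.get(k) or cut_clusters(dend, k)

    if config.bootstrap_B > 0:
        log.info("Step 4: bootstrap Jaccard stability (B=%d)", config.bootstrap_B)
        solution.jc_per_cluster = bootstrap_jaccard(
            panel, k, B=config.bootstrap_B, seed=config.seed, dialect=config.dialect,
            norm=config.norm, D=D, reference=solution,
        )
    labels = interpret_quality(solution)
    quality_rows = []
    for c in sorted(solution.sizes):
        jc = None if solution.jc_per_cluster is None else solution.jc_per_cluster.get(c)
        quality_rows.append(
            dict(cluster=c, N=solution.sizes[c],
                 ASWw=solution.asww_per_cluster.get(c) if solution.asww_per_cluster else None,
                 JC=jc, interpretation_asww=labels[c].asww_label,
                 interpretation_jc=labels[c].jc_label or "")
        )
    pd.DataFrame(quality_rows).to_csv(out / "quality.csv", index=False)
    pd.DataFrame(
        [dict(k=kk, asww=s.asww_overall, min_size=min(s.sizes.values()), admissible=s.admissible)
         for kk, s in sorted(report.solutions.items())]
    ).to_csv(out / "solutions.csv", index=False)
    pd.DataFrame(sorted(solution.assignment.items()), columns=["id", "cluster"]).to_csv(
        out / "assignment.csv", index=False
    )

    # --- Step 6: trajectory-model cross-validation -------------------------
    gbmt_ks = config.gbmt_k_range or list(k_range)
    log.info("Step 6: trajectory mixture models, K in %s", gbmt_ks)
    spec = GbmtSpec(poly_degree=config.gbmt_degree, n_starts=config.gbmt_starts,
                    max_iter=config.gbmt_max_iter, tol=config.gbmt_tol, seed=config.seed)
    chosen, table, _fits = select_gbmt(panel, gbmt_ks, spec, min_prop=config.min_prop)
    table.to_csv(out / "gbmt_comparison.csv", index=False)
    overlap_path = out / "overlap.csv"
    if chosen is not None:
        gb_assign = posterior_assign(chosen)
        pd.DataFrame(sorted(gb_assign.items()), columns=["id", "subgroup"]).to_csv(
            out / "gbmt_assignment.csv", index=False
        )
        coef_rows = [
            dict(group=g + 1, outcome=("therapy", "counseling", "medication")[j], term=p,
                 beta=chosen.beta[g, j, p])
            for g in range(chosen.K) for j in range(3) for p in range(chosen.beta.shape[2])
        ]
        pd.DataFrame(coef_rows).to_csv(out / "gbmt_coefficients.csv", index=False)
        overlap = participant_overlap(solution.assignment, gb_assign)
        prof_a = modal_profile(solution.assignment, panel)
        prof_b = modal_profile(gb_assign, panel)
        rows = []
        for c in overlap.counts.index:
            for g in overlap.counts.columns:
                dems_a = [panel.demographics[i] for i, cc in solution.assignment.items() if cc == c]
                dems_b = [panel.demographics[i] for i, gg in gb_assign.items() if gg == g]
                entry = match_criteria(
                    (prof_a.modal_state[c], prof_a.majority_use[c]),
                    (prof_b.modal_state[g], prof_b.majority_use[g]),
                    float(overlap.pct_a_in_b.loc[c, g]),
                    dems_a, dems_b, MatchCriteria(), cluster=int(c), subgroup=int(g),
                )
                rows.append(
                    dict(cluster=int(c), N_cluster=int(overlap.a_sizes[c]), subgroup=int(g),
                         N_subgroup=int(overlap.b_sizes[g]),
                         shared=int(overlap.counts.loc[c, g]),
                         pct_cluster_in_subgroup=round(float(overlap.pct_a_in_b.loc[c, g]), 1),
                         pct_subgroup_in_cluster=round(float(overlap.pct_b_in_a.loc[c, g]), 1),
                         criterion1=entry.criterion1_pass, criterion2=entry.criterion2_pass,
                         criterion3=entry.criterion3_pass, criterion4=entry.criterion4_pass,
                         matched=entry.matched)
                )
        pd.DataFrame(rows).to_csv(overlap_path, index=False)

    # --- Step 5: sensitivity ------------------------------------------------
    for mode in config.sensitivity:
        log.info("Step 5: sensitivity analysis (%s)", mode)
        sens = run_sensitivity(panel, solution, mode, norm=config.norm, dialect=config.dialect,
                               k_range=k_range, min_prop=config.min_prop)
        pd.DataFrame(
            [dict(mode=mode, n=sens.panel.n, ari=sens.comparison.ari,
                  n_dropped=len(sens.dropped),
                  **{f"jc_cluster_{c}": j for c, j in sens.comparison.best_jaccard.items()})]
        ).to_csv(out / f"sensitivity_{mode}.csv", index=False)

    # --- Step 7: profiles ----------------------------------------------------
    log.info("Step 7: cluster descriptives and demographic comparisons")
    state_distribution(solution.assignment, panel).to_csv(out / "state_distribution.csv", index=False)
    usage_curves(solution.assignment, panel).to_csv(out / "usage_curves.csv", index=False)
    subset = [c for c in sorted(solution.sizes) if (solution.asww_per_cluster or {}).get(c, 0) >= 0.26]
    if len(subset) < 2:
        subset = sorted(solution.sizes)
    prof = profile_table(panel, solution.assignment, clusters_subset=subset)
    prof.to_csv(out / "demographic_comparisons.csv", index=False)

    manifest = dict(
        package_version=__version__,
        config=dataclasses.asdict(config),
        config_sha256=config.digest(),
        seed=config.seed,
        chosen_k=int(k),
        n_individuals=panel.n,
        versions=dict(numpy=np.__version__, pandas=pd.__version__),
        compared_clusters=subset,
    )
    from .io import write_json

    write_json(manifest, out / "manifest.json")
    config.to_yaml(out / "config.yaml")
    return PipelineResult(outdir=out, panel=panel, solution=solution, report=report,
                         gbmt_fit=chosen, manifest=manifest)
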
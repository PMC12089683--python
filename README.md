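# careseq

Longitudinal sequence analysis of mental-health intervention use.

Many adults — in the motivating application, autistic adults without
intellectual disability — use therapy, counseling and/or psychotropic
medication over many years, in changing combinations.  `careseq` implements
a complete pipeline for identifying the dominant multi-year *intervention
trajectories* in such panel data and validating them:

1. **State sequences.** Each year's three binary indicators (therapy T,
   counseling C, medication M) define one of 8 joint states
   (1 = none, 2 = T, 3 = C, 4 = M, 5 = T&C, 6 = T&M, 7 = C&M, 8 = T&C&M; an
   optional state 9 codes a missing wave).  Intermittent missing years are
   filled from the nearest observed neighbours; individuals need at least
   five *consecutive* observed years; sequences (length 5–7) are
   left-aligned at T1 so that the *order* of states, not their calendar
   timing, drives the analysis.
2. **Dissimilarity.** The longest-common-subsequence distance
   d(x, y) = |x| + |y| − 2·LCS(x, y), normalized for length differences
   (default 1 − LCS/√(|x|·|y|)).
3. **Clustering.** Agglomerative clustering with Ward's criterion on the
   dissimilarity matrix.  Solutions with any cluster below 10% of the
   sample are inadmissible; admissible solutions are ranked by the weighted
   average silhouette width ASWw ∈ [−1, 1]; cluster stability is the mean
   bootstrap Jaccard coefficient JC ∈ [0, 1].
4. **Cross-method validation.** A group-based multivariate trajectory
   (GBMT) mixture — K latent groups, each with polynomial logistic
   trajectories for the three binary outcomes, fitted by EM and selected by
   BIC/AIC under the same 10% rule — is compared to the sequence-analysis
   clusters by four explicit criteria (similar modal trajectory, matching
   majority usage on ≥ half the years for each intervention kind, ≥ 75%
   member overlap, shared demographic profile).
5. **Sensitivity analyses.** Re-runs without the 2020–2021 pandemic years,
   and with missing waves as an explicit ninth state; partitions are
   compared by the adjusted Rand index.
6. **Profiles.** Per-cluster state distributions over time and demographic
   comparisons (χ² with Cramér's V, one-way ANOVA with η², Bonferroni
   post hocs).

Because the registry data behind the motivating study cannot be
redistributed, the package ships a synthetic-cohort generator
(`careseq.cohort`): a mixture of trajectory archetypes, each a first-order
Markov chain over the 8 states with its own demographic profile,
intermittent missingness and attrition, plus ground-truth labels so every
downstream stage can be scored against a known answer.

## Worked example

```python
from careseq import (default_config, generate_cohort, fill_intermittent, build_panel,
                     distance_matrix, ward_linkage, select_solution, bootstrap_jaccard,
                     interpret_quality)

cohort = generate_cohort(default_config(n=445, seed=1))
panel = build_panel([fill_intermittent(r) for r in cohort.records])
print(f"{panel.n} eligible individuals, lengths {sorted(set(panel.lengths))}")

D = distance_matrix(panel, norm="gmean")
report = select_solution(D, k_range=range(2, 9))
for k in report.ranked_admissible[:3]:
    sol = report.solutions[k]
    print(f"k={k}: ASWw={sol.asww_overall:.2f}, min cluster size={min(sol.sizes.values())}")

best = report.best
best.jc_per_cluster = bootstrap_jaccard(panel, best.k, B=100, seed=1, D=D, reference=best)
labels = interpret_quality(best)
for c in sorted(best.sizes):
    print(f"cluster {c}: N={best.sizes[c]:3d}  ASWw={best.asww_per_cluster[c]:.2f} "
          f"({labels[c].asww_label})  JC={best.jc_per_cluster[c]:.2f} ({labels[c].jc_label})")
```

prints

```
439 eligible individuals, lengths [5, 6, 7]
k=5: ASWw=0.69, min cluster size=56
k=4: ASWw=0.63, min cluster size=77
k=3: ASWw=0.53, min cluster size=93
cluster 1: N=142  ASWw=0.77 (strong)  JC=0.94 (highly stable)
cluster 2: N= 93  ASWw=0.89 (strong)  JC=0.96 (highly stable)
cluster 3: N= 77  ASWw=0.76 (strong)  JC=0.95 (highly stable)
cluster 4: N= 71  ASWw=0.09 (none)  JC=0.86 (highly stable)
cluster 5: N= 56  ASWw=0.77 (strong)  JC=0.91 (highly stable)
```

Six of the 445 simulated individuals fail the five-consecutive-years rule
after gap filling and are excluded.  The five-cluster solution ranks first
among admissible solutions by overall silhouette width; four clusters
recover the four named archetypes with strong internal structure, while
cluster 4 absorbs the heterogeneous remainder — coherent membership under
resampling (high JC) but essentially no silhouette structure (ASWw ≈ 0.1),
the signature of a "catch-all" cluster.

The same analysis is available from the shell:

```sh
careseq run --seed 1 --outdir run1          # full pipeline, all artifacts as CSV
careseq simulate --out cohort.csv --n 445 --seed 1
careseq prepare  --input cohort.csv --out panel.csv
careseq distances --panel panel.csv --out d.csv
careseq cluster  --matrix d.csv --out assignment.csv
```

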
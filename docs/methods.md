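# Methods

## Data model

The unit of analysis is an individual observed yearly over a 2015–2021
panel.  A wave is *observed* when all three intervention indicators
(therapy, counseling, medication) are reported; a wave with any missing
indicator is treated as a missing wave, because the joint state is
undefined otherwise.  A lenient reading that imputes a single missing
indicator as "no" would change the state alphabet semantics and is
deliberately not the default.

**Gap filling.** Only intermittent gaps — waves with at least one fully
observed wave both before and after — are filled; leading and trailing
gaps never are.  Filling acts per indicator on the original values: if the
nearest observed values on both sides agree, the gap takes that value;
on disagreement the configurable tie rule applies (`carry_forward` by
default, i.e. the earlier value wins; `carry_backward` and `leave` are
available).  Gaps longer than one year are filled by the same
nearest-neighbour rule.  The operation is idempotent and never touches
observed values (property-tested).  The exact rule used in the motivating
study is not recoverable from its main text, so the rule here is the most
conservative reading of "filled from surrounding years" and is pluggable.

**Eligibility and alignment.** Individuals need a run of at least five
consecutive observed waves (counted *after* filling — the alternative,
counting only originally observed waves, is stricter and can be obtained
by skipping the fill step).  The sequence taken forward is the longest such
run (earliest on ties), clipped to seven waves, re-indexed to start at T1.
Calendar years are kept as sequence metadata so the pandemic-years
sensitivity analysis can address chronological years despite left
alignment.  Panel invariants: lengths in {5, 6, 7}, length spread ≤ 2.

## Dissimilarity

LCS distance d(x, y) = |x| + |y| − 2·LCS(x, y), computed by the standard
O(|x|·|y|) dynamic program.  This is a metric (symmetry, identity,
triangle inequality are property-tested and re-verified by the acceptance
script).  Normalizations:

- `gmean` (default): 1 − LCS/√(|x|·|y|) ∈ [0, 1].  The geometric-mean form
  is the standard automatic choice for LCS-type distances in the sequence
  analysis literature and absorbs the ≤ 2-wave length differences.
- `maxlength`: d/(|x| + |y|), i.e. distance over its maximum attainable
  value for the pair; kept for sensitivity checks.
- `none`: raw distance.

Distances are stored at full precision; identical sequences are
deduplicated before the pairwise pass (cohorts concentrate on few distinct
trajectories), which also lets bootstrap resamples reuse the full-panel
matrix by row/column subsetting — an exact shortcut, not an approximation.

In the nine-state sensitivity analysis the missing state is an ordinary
alphabet symbol: two missing waves count as a match.  This is intentional
(individuals with similar missingness patterns are drawn together) and is
the point of that analysis — attrition-driven structure shows up as a
changed partition.

## Clustering and validation

**Ward linkage** is implemented via the Lance–Williams recurrence with two
dialects: `ward_d2` (default) squares the dissimilarities before the
recurrence and reports square-rooted merge heights; `ward_d` runs on raw
dissimilarities.  The motivating analysis does not name its variant, so
both are exposed.  Equal-cost merges (common with discrete LCS distances)
break toward the pair containing the smallest leaf id, making dendrograms
deterministic across platforms.  Cutting undoes the last k − 1 merges;
labels 1..k are ordered by decreasing cluster size.

**Quality.** Silhouette s(i) = (b − a)/max(a, b) with a the mean
within-cluster dissimilarity (self excluded) and b the best other-cluster
mean; members of singleton clusters get s = 0 (convention; the source
analysis is silent).  ASWw is the weighted mean (unit weights by default,
in which case ASWw equals the plain ASW).  Interpretation bands: ≥ 0.71
strong, 0.51–0.70 reasonable, 0.26–0.50 weak (band boundaries inclusive),
< 0.26 none.

**Admissibility.** A k-solution is admissible iff every cluster holds at
least ⌈0.10·n⌉ individuals.  All solutions in the examined range
(default k = 2..8) are reported with their admissibility and ASWw ranking;
the package never silently auto-picks, because the final choice also
weighs stability and interpretability.

**Stability.** Bootstrap Jaccard follows the classic cluster-wise
stability scheme: resample individuals with replacement, re-cluster at the
same k (fixed, not re-selected — the conservative default), and score each
original cluster by its best Jaccard overlap with any resample cluster,
computed over bootstrap positions so duplicates count.  Bands: ≥ 0.85
highly stable, 0.75–0.85 stable, 0.60–0.75 clear pattern, 0.50–0.60
unstable, < 0.50 dissolved.

## Trajectory mixture (GBMT)

K latent groups; within group k outcome j at time t is Bernoulli with
logit(p) = Σ_p β_kjp z_t^p, with z the time index standardized to mean 0
and unit range and polynomial degree 2 by default.  Outcomes and time
points are conditionally independent given the group; missing waves
contribute nothing to the likelihood, which is how 5-to-7-wave sequences
coexist.  The reference trajectory-mixture literature is formulated for
continuous outcomes; with binary indicators the logistic family is the
faithful model class, so it is the implementation here.

Fitting is EM: responsibilities in the E-step; the M-step updates mixing
weights as mean responsibilities and the β by responsibility-weighted
logistic regression (damped Newton with step-halving, ridge 10⁻⁸), so each
M-step provably does not decrease the penalized objective and the whole
procedure is a monotone generalized EM.  The observed-data log-likelihood
is asserted non-decreasing with an absolute float tolerance of 10⁻⁶
(exact-arithmetic EM is monotone; the ridge plus finite Newton stopping
leaves O(10⁻⁸) wiggle at convergence).  Defaults: 10 random starts
(Dirichlet-initialized responsibilities), tolerance 10⁻⁶ on the
log-likelihood gain, max 500 iterations, responsibilities floored at
10⁻¹² without renormalization.  Starts that collapse a group below 1/n
mass are redrawn and counted.  Groups are reported sorted by decreasing
mixing weight.  Free parameters for BIC/AIC: (K − 1) + 3K(degree + 1).
Model order is chosen as the lowest BIC among fits whose smallest
modal-assignment group satisfies the same 10% rule; AIC disagreement is
flagged, never silently resolved.

## Cluster/subgroup correspondence

Four criteria, each with an explicit numeric surrogate because the source
describes them qualitatively:

1. modal-state agreement on ≥ 50% of the compared time points (the raw
   agreement fraction is always reported alongside);
2. for each intervention kind, the group-majority usage flag agrees on at
   least ⌈T/2⌉ of the T compared years;
3. at least 75% of the cluster's members in the subgroup (strict: 74.9
   fails);
4. no demographic variable differs beyond threshold — standardized mean
   difference < 0.5 for continuous covariates, maximum per-category
   proportion gap < 0.2 for categorical ones; the per-variable numbers are
   always emitted so users can apply their own judgment.

Unequal time horizons are compared over the shorter one.  Partition-level
similarity uses the adjusted Rand index plus per-cluster best-match
Jaccard.

## Demographic comparisons

Pearson χ² without continuity correction (Cramér's V = √(χ²/(n·(min(r,c)−1))))
for categorical variables; one-way fixed-effects ANOVA (η² = SSB/SST, not
ω², matching the effect-size convention of the motivating report) for
continuous ones.  Post hocs are pairwise two-group χ² / pooled-variance t
tests with Bonferroni adjustment over all pairs in the compared subset
(family size printed).  Everything is complete-case per variable with the
denominator reported, since missingness differs by covariate.  Sex is
compared as two-level (female/male) by default; additional responses are
kept descriptively but excluded from the test because tiny cells make a
three-level test degenerate.

## Synthetic cohorts

The generator emulates the *structure* of the motivating registry sample,
not its values: n = 445; five archetypes mixed in the empirical cluster
proportions (125/51/100/84/85 of 445) — least intervention, mostly
counseling, mostly medication, mixed counseling & medication, and a
heterogeneous remainder; archetype-specific demographics taken from the
reported per-cluster summaries (e.g. 36% female and 17% psychiatric
co-occurrence in the least-intervention archetype vs 64%/62% in the mixed
one); observed lengths drawn from {5: 0.30, 6: 0.25, 7: 0.45} (the 7-wave
share matches the reported 201/445 complete cases; the 5/6 split is
unreported and was fixed once); intermittent missing rate 0.02 (such gaps
were rare enough to be filled by hand in the source study); attrition
hazard 0 by default because the length distribution is drawn directly —
set it above 0 (it acts from the sixth wave on) to study monotone dropout
explicitly.

Dynamics are first-order Markov on the joint 8-state alphabet:
row = 0.80·stay + 0.20·archetype preference (0.45 stay for the
heterogeneous archetype).  Preference vectors put ≈ 0.92–0.94 mass on the
archetype's dominant state.  This was set so that planted structure is
genuinely recoverable — the package's recovery tests demand adjusted Rand
≥ 0.8 at default separation — and it makes synthetic cohorts *cleaner*
than real registry data: silhouette widths on default cohorts run ≈ 0.7–0.9
where the motivating study saw 0.01–0.64.  Passing recovery tests here
therefore demonstrates correctness of the machinery, not that real cohorts
cluster this sharply.  The generator also does not emulate: measurement
error in self-report, covariate-dependent attrition (the hazard is
constant), year effects (dynamics are stationary — which is exactly why
the pandemic-drop sensitivity check must be ARI-stable on synthetic data),
or any calibration of transition matrices to real prevalences (none are
published).

One integer seed drives named substreams (assignment, dynamics,
demographics, missingness), so stages can be varied independently and
every run is exactly reproducible.

## Problem sizes in the validation suite

The test and acceptance runs use: 30-sequence brute-force LCS checks
(435 pairs), 1000 metric triples, 200 silhouette instances, five planted
cohorts of n = 445 with a 100-resample bootstrap, a 600-individual
two-group mixture recovery, order selection over K = 1..6 with four EM
starts, 200 χ²/ANOVA oracle instances plus 2000 null tables, and a
300-individual stationary cohort for the sensitivity invariances.  These
sizes give stable pass/fail behavior across seeds while keeping a full run
in the tens of seconds on one CPU.

## Known limitations

- The fill rule and the exact Ward dialect/normalization of the motivating
  analysis are unrecoverable from its text; all variants are config flags,
  defaults chosen as documented above.
- No multiple imputation (rejected in the source design) and no
  covariate-dependent mixing in the trajectory model.
- The 10% admissibility rule is applied to modal-assignment group sizes;
  applying it to posterior mass instead would be a one-line change but is
  not exposed.
- Bootstrap stability re-clusters at fixed k; re-running model selection
  inside each resample would measure a different (stricter) notion of
  stability.
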
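# Methods

This note documents the models, numerical conventions and design choices
behind `mlclust`, and what the synthetic cohorts do and do not emulate.

## Layers and slope descriptors

A cohort is analysed through two row-aligned matrices. The **baseline
layer** holds 26 descriptors measured at study entry ("baseline" means the
earliest visit, whether labelled screening or baseline): demographics and
APOE4 allele count, cognitive/functional scales (CDR-SB, ADAS-Cog 11/13,
MMSE, MOCA, FAQ, the RAVLT subscores, logical-memory delayed recall),
FreeSurfer-style regional volumes (ventricles, hippocampus, whole brain,
entorhinal, fusiform, medial temporal, ICV), PET SUVRs (FDG, AV45) and CSF
proteins (Aβ42, total tau, p-tau). The exact 26-descriptor roster is a
configurable schema; the default follows the variables conventionally
reported for this population, and the 17 longitudinal base measures (10
clinical + 7 imaging) are fixed by the `S`-prefixed slope naming scheme.

A **slope descriptor** `SX` is the ordinary-least-squares slope of measure
`X` against visit month, using all available time points, multiplied by 6 —
the mean change per 6-month period, in the measure's own units. Slopes need
two non-missing points at distinct months; otherwise the cell is missing
(no exception). Follow-up is capped at 60 months so differently recruited
cohorts share one observation window.

Missing cells are median-imputed per descriptor **only** for the similarity
computation; every reported statistic uses the raw values. A
fully-missing descriptor is a configuration error rather than silently
imputable. The imputation mask is kept on the imputed layer for audit.

## Rule-coverage similarity (EST)

Similarity is learned, not assumed. The negatives of the artificial task
are built by resampling each column independently from its own empirical
values: every marginal is preserved exactly, so no single-descriptor split
can separate the classes — the ensemble is forced to model the
*dependence* structure, which is where cluster structure lives. The
default learner is `T = 100` bagged decision trees of depth ≤ 4 with √d
feature subsampling, balanced negatives (`m = N`), and one rule per
positive-enriched leaf (positive coverage rate strictly above negative
coverage rate on the tree's bootstrap resample; conditions along a path
are collapsed to the tightest bound per (descriptor, relation), so a rule
holds at most a lower and an upper bound per descriptor). All knobs are in
`RuleLearnerParams`. Attributes enter untransformed: threshold rules are
scale-free, so standardisation would only relabel thresholds.

`x_ij` is the fraction of rules covering both subjects; `x_ii = 1` by
convention, and the diagonal never enters any variability sum. ESTs beyond
1000 subjects are outside the regime this construction was designed for
and trigger a warning.

## The clustering objective and algorithm

For subject `i` in cluster `C`, within- and outside-cluster variability
are sums of squared deviations of row-`i` similarities around their
respective means (singleton ⇒ within term 0; empty outside set ⇒ 0). The
merge gain is `DIFF_xy = CRV_x + CRV_y − CRV_{x∪y}`, evaluated with all
other clusters unchanged — only members of `x ∪ y` change their breakdown,
which is also why cached pair gains stay valid across unrelated merges.
The printed form of this criterion in the source literature contains an
obvious typographical slip (it reduces to `CRV_x`); the implemented form
is the only one under which "positive iff merging reduces variability"
holds.

Numerical conventions, each of which was a genuinely open choice:

- **Joint rule**: min of per-layer DIFFs, generalised to k ≥ 1 layers.
- **Stopping**: merge only while the max joint DIFF is strictly positive;
  `DIFF = 0` does not merge.
- **Tie-break**: among equal maximal DIFFs, the lexicographically smallest
  (min id, max id) pair; merged clusters get fresh ids, so the order is
  deterministic and permutation of subjects permutes the result.
- **Fast path**: per-cluster row aggregates (Σx, Σx²) give O(|x|+|y|) pair
  evaluation and a closed-form matrix for the all-singletons start; the
  aggregates reproduce a full recomputation to ~1e-14 (verified against a
  brute-force oracle in the tests), with `max(·, 0)` clamping of the
  `Σx² − (Σx)²/n` form against negative floating-point dust.
- **Unclustered**: final clusters below `min_size = 20` (configurable) are
  flagged unclustered; named clusters are ranked by size.

One consequence of the strict stop rule worth knowing: with two layers
whose block structures fully contradict each other, singleton variability
is still large enough that cross-block merges carry positive joint DIFF
(all first-step pairs tie at +1/3 on the worked 4×4 fixtures), so
contradiction between layers does *not* freeze the algorithm at
singletons; it produces a compromise partition through the tie-break.

## Profiling, network, classifiers

Cluster contrasts use the Mann–Whitney rank-sum test: tie-corrected normal
approximation without continuity correction, switching to exact
enumeration of all group assignments when the pooled sample size is ≤ 10;
z is reported unsigned, p two-sided, no multiplicity correction by default
(a Benjamini–Hochberg column is available but off, mirroring
per-descriptor reporting practice). APOE4 is dichotomised to carrier
status and tested with the uncorrected Pearson chi-square,
`n(ad−bc)²/(r₁r₂c₁c₂)`, df = 1.

Transitions: a subject counts as *converted* if any visit diagnosis is
Dementia, *reverted* if any visit is CN and none is Dementia (dementia
outranks reversion when both occur), else *stable*; subjects with no
post-baseline diagnosis count as stable and are logged.

The correlation network uses pairwise-complete Spearman correlations
(≥ 3 complete pairs, else undefined), inclusive absolute-value threshold
`|rho| ≥ 0.5` — strongly anti-correlated scales such as a score and an
error count belong in the network — and edge length `1/|rho|`. Export is
GraphML with role (baseline/slope, by the `S` prefix) and category
attributes; layout is left to downstream tools.

Cut-off classifiers label the rapid cluster positive and everyone else —
including the unclustered — negative. Candidate thresholds are the
midpoints between consecutive distinct observed values (no achievable
confusion table is missed, a step-function argument tested explicitly);
the search maximises Youden's J = sensitivity + specificity − 1, ties
broken toward higher specificity then lower threshold, with an exhaustive
grid for two-condition conjunctions. The quality function is a choice:
subgroup discovery literature does not fix one, and J is symmetric in the
two metrics actually reported. Classifiers are frozen after training and
validated on a disjoint cohort tag.

## The synthetic generator

The generator reproduces the statistical skeleton of a two-cluster late-MCI
cohort: group sizes 240 (rapid) / 184 (slow) / 138 (diffuse remainder);
per-descriptor group means and SDs set to the published per-cluster
summaries, with whole-sample or clinic-scale values for descriptors that
lack a per-cluster summary (notably ADAS-11, RAVLT subscores,
logical-memory recall, fusiform and ICV — documented in
`synthetic_cohort.py`); APOE4 carrier prevalence 49% / 77%; sex fractions
per group; study-tag assignment at the two cohorts' relative sizes.

Covariance model: within a group, descriptors are plainly equicorrelated
at `rho_w` (default 0.2) through one shared standard-normal factor per
layer; the baseline and slope factors correlate at `layer_coupling`
(default 0.4, in the range of the published baseline-biomarker versus
clinical-slope correlations). The unclustered group is drawn wide —
means centred between the two clusters, SDs 1.5× the wider cluster SD,
`rho_w = 0` — so it resists confident assignment.

Longitudinal measures are synthesised as visit series on the 0–60-month
6-monthly grid: value = baseline draw + (slope/6)·month + N(0, σ) noise
(σ = 2× the slope SD in measure units; the entry measurement is noise-free
so the baseline layer matches its configured moments exactly). The drawn
slope SD is shrunk by the variance the visit noise adds to the fitted
slope (`36σ²/S_xx`), so the *realized* OLS slopes match the configured
(mean, SD). The slope layer downstream is computed by the real estimator —
the generator never writes slope values directly.

Diagnoses follow per-visit hazards derived from 5-year cumulative
probabilities (conversion 64% / 13% / 42%-consistent for the remainder;
reversion 0% / 10% / small), with Dementia and CN absorbing. Missingness
is block-structured per subject: CSF present for ~54%, amyloid PET ~28%,
FDG ~64%, matching the reported biomarker subsample fractions.

What the generator does **not** emulate: staggered dropout (all subjects
are followed the full 60 months by default; a dropout knob is not
provided), non-Gaussian and heavy-tailed marginals, multi-factor
within-group covariance, and visit-to-visit autocorrelated measurement
error. Tests passing on these cohorts therefore demonstrate algorithmic
correctness and calibration under a clean factor-Gaussian emulation, not
performance on real clinical data.

## Known limitations: recovery under published within-cluster spread

The published *within-cluster* SDs of the slope descriptors are of the
same order as the between-cluster mean differences (e.g. CDR-SB slope
0.1 ± 0.4 vs 0.7 ± 0.8 per 6 months). Under the generator's Gaussian
model this puts the slope layer's pooled Mahalanobis separation at
Δ² ≈ 5.9 — a Bayes-optimal two-group accuracy of ~89%, an adjusted-Rand
ceiling of ~0.6 for any partition the slope layer must endorse. Because
the min rule makes every merge answer to the slope layer, end-to-end
recovery of the planted two-cluster structure saturates well below
ARI 0.8 at n = 200 (typically 0.1–0.45), with the agglomeration instead
finding *slope-homogeneous sub-clusters* of the planted groups — nearly
pure in the planted label, split by slope. This is a property of the
study conditions, not an implementation defect: the original clusters
were themselves defined by this algorithm on real data, so their
within-cluster similarity structure was tight by construction, a
circularity a moment-matched Gaussian cohort cannot reproduce. The
acceptance suite measures and reports this honestly rather than relaxing
the conditions.

Reported problem sizes: the acceptance script runs the full 562-subject
study configuration once and the 200-subject two-cluster recovery
benchmark over 10 seeds; the test suite uses cohorts of 100–424 subjects
and brute-force oracles at N ≤ 12.
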
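# mlclust — multilayer clustering of longitudinal at-risk cohorts

`mlclust` stratifies a longitudinal cohort of subjects at risk of dementia
(mild cognitive impairment, MCI) into prognostically distinct subgroups and
learns simple cut-off classifiers that flag rapid decliners. It is aimed at
biostatisticians and method researchers working with ADNIMERGE-style
subject-visit tables: cognitive and functional scales, MRI volumetry, PET
SUVRs, CSF proteins, and clinician diagnoses reassessed at 6-month visits.

## The method

The cohort is viewed through two **data layers**: a baseline layer of 26
descriptors measured at entry, and a prognostic layer of 17 slope
descriptors `SX` — the 6-monthly change of measure `X`, estimated per
subject by simple linear regression over all available visits.

For each layer an **example similarity table** (EST) is computed: an
artificial classification task opposes the original subjects (positives) to
per-column randomized copies of them (negatives, which keep every marginal
but destroy the dependence structure). An ensemble of bagged, depth-limited
decision trees is fitted to this task and every root-to-leaf path ending in
a positive-enriched leaf becomes one conjunctive threshold rule. The
similarity of subjects *i*, *j* is the proportion of rules covering both,
`x_ij ∈ [0, 1]`, with `x_ii = 1`.

Clustering minimises the **clustering-related variability**. For subject
*i* in cluster *C*,

    CRV_i = CRV_i,wc + CRV_i,oc
    CRV_i,wc = Σ_{j∈C, j≠i} (x_ij − x̄_wc)²      (within-cluster)
    CRV_i,oc = Σ_{j∉C}      (x_ij − x̄_oc)²      (outside-cluster)

and `CRV_C = Σ_{i∈C} CRV_i`. Merging clusters *x*, *y* changes the
objective by `DIFF_xy = CRV_x + CRV_y − CRV_{x∪y}`; with several layers the
**joint DIFF is the minimum across layers**, so a merge must pay off in
every layer. Agglomeration starts from singletons and repeatedly merges the
pair with the maximal joint DIFF while it is strictly positive. Small final
clusters are flagged *unclustered*; the remaining clusters are profiled
(Mann–Whitney / chi-square contrasts, MCI→dementia conversion and MCI→normal
reversion rates), a Spearman correlation network (`|rho| ≥ 0.5`,
`dist = 1/|rho|`) is exported as GraphML, and subgroup-discovery threshold
search (Youden's J) learns 1–2-condition cut-off classifiers for the rapid
decliners, trained on one study cohort and validated frozen on the other.

Because the cohorts this method was designed for are restricted-access, the
package ships a first-class synthetic generator: two planted decliner
clusters plus a diffuse remainder with published group means/SDs, visit
series whose slopes are estimated by the real pipeline path, block-missing
CSF/PET descriptors, and per-visit diagnosis transition hazards.

## Worked example

```python
import mlclust as m

# a 200-subject cohort with two planted decliner clusters
cfg = m.default_config(n_rapid=113, n_slow=87, n_unclustered=0, seed=7)
syn = m.generate(cfg)

layer1, layer2 = m.build_layers(syn.cohort)          # 200×26 and 200×17
est1 = m.compute_est(m.impute_for_similarity(layer1), seed=1)
est2 = m.compute_est(m.impute_for_similarity(layer2), seed=2)
trace = m.cluster([est1, est2])
clustering = m.label_unclustered(trace, min_size=20)
print({c: clustering.size_of(c) for c in clustering.named_clusters},
      clustering.size_of("unclustered"))
```

prints

```
{'C1': 42, 'C2': 38, 'C3': 32, 'C4': 26, 'C5': 25} 37
```

five named clusters (C2, C3 are purely slow decliners; C4, C5 almost purely
rapid; C1 mixed) plus 37 subjects left in sub-threshold clusters.
The baseline layer separates the planted groups sharply; the slope layer —
whose published within-cluster SDs are of the same order as the group
difference — carries genuine sub-structure, so the min rule splits rather
than pools the groups (see `docs/methods.md` for why this is expected).
Profiling the truth groups of the same cohort:

```python
labels = [syn.truth[s] for s in syn.cohort.subjects]
report = m.transition_rates(syn.cohort,
                            m.Clustering(labels, list(syn.cohort.subjects)))
print(round(report.per_cluster["rapid"].conversion_pct, 1),
      round(report.per_cluster["slow"].conversion_pct, 1))
```

```
69.0 12.6
```

i.e. roughly the 5-year 64% / 13% conversion hazards the generator encodes.

The same analysis runs from the shell:

```sh
mlc synth --seed 17 --n-rapid 113 --n-slow 87 --n-unclustered 0 \
    --out cohort.csv --truth truth.csv
mlc run --config run.yaml          # full pipeline from a YAML config
mlc cluster --est est_a.csv --est est_b.csv --out clusters.csv
```

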
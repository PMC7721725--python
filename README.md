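# methorigin

Methylation-array analysis of tumour cell of origin, built around the
question that motivates it: pancreatic neuroendocrine tumours (PanNETs)
arise in the islets of Langerhans, but whether a given tumour derives
from an alpha-cell, a beta-cell, or neither is invisible to routine
histology — and it matters, because the origin classes differ in
mutation spectrum and relapse risk. Given 450K-style beta values
(probes x samples, values in [0, 1]) for tumours and sorted reference
cell types, the package:

- filters and normalizes the matrix (autosomal filtering, BMIQ-style
  type II correction, ComBat-style batch adjustment on logit scale);
- finds differentially methylated CpGs between sorted alpha- and
  beta-cells with an empirical-Bayes moderated t test
  (adj p < 0.001, |Δβ| > 0.2);
- builds neighbor-joining phyloepigenetic trees on 1 − Pearson
  distances, rooted at a beta-cell reference;
- estimates each tumour's cell-type composition by constrained
  projection onto reference profiles (min ‖y − Mw‖², w ≥ 0, Σw ≤ 1;
  500 markers screened from 10,000 CpGs) and calls alpha-like /
  beta-like / intermediate via the 65% similarity rule;
- scores methylation of alpha/beta transcription-factor checkpoint
  regions gated by islet chromatin states;
- runs Monti consensus clustering (pItem 0.8, Pearson distance,
  ward.D2 inner / average final linkage) with stability-based
  selection of the number of subtypes;
- infers arm-level copy number from total probe intensities (adaptive
  ≥15-probe bins, arm medians, Ward/Euclidean grouping into burden
  tiers);
- compares disease-free survival across groups (Kaplan-Meier,
  log-rank).

A bundled synthetic-methylome generator (`methorigin.simulate`) emits
cohorts with exactly this structure — planted markers, mixtures,
batches, type II compression, arm events, group hazards — plus full
ground truth, so the whole pipeline is testable without any download.

## Worked example

```python
from methorigin import (
    SimulationConfig, simulate_cohort,
    select_markers, estimate_fractions, classify_origin,
)

cohort = simulate_cohort(SimulationConfig(seed=2))
ref = select_markers(cohort.reference_beta, cohort.reference_sheet,
                     n_screen=10_000, n_markers=500)
fractions = estimate_fractions(cohort.tumour_beta.values, ref)
calls = classify_origin(fractions, threshold=65.0)

truth = cohort.ground_truth.sample_truth["group"]
print((100 * fractions.groupby(truth)[["alpha", "beta"]].mean()).round(1))
print(calls["label"].value_counts().to_dict())
```

This prints the mean percent similarity of each planted tumour group to
the alpha- and beta-cell references, and the origin calls:

```
                  alpha  beta
group
alpha_like         71.6   0.1
beta_like           0.1  72.6
intermediate_ADM   52.7  11.9
intermediate_WT    50.7  14.0
{'intermediate': 92, 'alpha_like': 19, 'beta_like': 14}
```

Alpha-like tumours project ~72% onto the alpha reference, beta-like
~73% onto beta, and the intermediate groups show the weak-alpha /
very-weak-beta pattern (≈51–53% / 12–14%) that motivates treating them
as a separate, higher-risk class. The 65% rule then recovers the
planted group sizes (19 / 14 / 92).

The same stages are available from the shell:

```bash
methorigin simulate --seed 1 --out cohort/
methorigin run-all --seed 1 --out results/
```

`run-all` writes per-stage artifacts (normalized matrices, DM table,
Newick tree, cell fractions, origin calls, consensus assignments, arm
copy-number table, BED bins, survival table) and a `summary.json` with
the headline numbers (group sizes, signature sizes, chosen k, CNA
group counts, log-rank result).

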
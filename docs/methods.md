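# Methods

`methorigin` implements a DNA-methylation framework for assigning
pancreatic neuroendocrine tumours (PanNETs) to a cell of origin
(alpha-like, beta-like or intermediate) and to prognostic subtypes,
starting from a 450K-style beta-value matrix. This note documents the
models, the numerical choices, and what the synthetic cohort does and
does not emulate.

## Data model

The central object is a probes x samples matrix of beta values
(methylated / total signal, in [0, 1]) with optional detection-pass
mask, accompanied by a probe annotation (chromosome, 1-based position,
type I/II design, chromatin state, nearest gene, chromosome arm) and a
sample sheet (batch, reference/tumour role, sorted cell type,
MEN1/DAXX/ATRX status, relapse time and event). Coordinates are 1-based
inclusive internally; only BED export converts to 0-based half-open.
Missing beta values are NaN, never sentinel numbers.

## Preprocessing

**Filtering** keeps autosomal probes, drops a user-supplied blacklist
(the cross-reactive/SNP lists in common use are curation products, so
they are input, not built-in), and removes probes whose missing
fraction exceeds a threshold. Filtering is idempotent.

**BMIQ-style type II normalization.** The two probe chemistries have
different beta distributions: type II values are compressed toward 0.5.
Per sample, a three-state (unmethylated / hemimethylated / methylated)
beta mixture is fitted by EM separately to type I and type II probes;
type II probes assigned to the U and M states are mapped through beta
quantile functions onto the corresponding type I component, and
H-state probes are rescaled linearly between the transformed U maximum
and M minimum (the dilation step). Type I probes pass through
unchanged. EM details: moment-matching M-steps, deterministic
initialization from fixed quantiles, convergence when the complete-data
log-likelihood changes by less than 1e-4 *per observation* (a
size-independent reading of the tolerance), at most 500 iterations;
non-convergence raises an error carrying the sample id and final
log-likelihood. Values are clipped to [1e-4, 1-1e-4] for the beta
densities.

**Batch adjustment** follows the parametric empirical-Bayes
location/scale model (ComBat). Betas are clamped to [1e-3, 1-1e-3] and
logit-transformed (M-value-like scale; variance-stabilizing and
unconstrained), per-probe batch location and scale effects are
estimated in a design that retains protected biological covariates,
shrunk across probes via a normal prior on locations and an
inverse-gamma prior on scales (moment-fitted), removed, and the result
back-transformed. One batch is a no-op; a batch with a single sample or
a batch perfectly confounded with a protected covariate is an error.

## Differential methylation

Per CpG, a two-group comparison on the beta scale (so the test and the
|Δβ| gate share a scale) with empirical-Bayes variance moderation: the
pooled residual variance is replaced by its posterior under a scaled
inverse-chi-square prior whose parameters are moment-fitted from the
distribution of log sample variances across probes (trigamma-inverse by
Newton iteration); t is referred to a t distribution with
prior-augmented degrees of freedom, and p values are
Benjamini-Hochberg adjusted. Selection uses strict inequalities,
adj p < 0.001 and |Δβ| > 0.2 by default, ordered by ascending adjusted
p, then descending |Δβ|, then probe id. Probes with fewer than two
non-missing values in a group are dropped with a logged count.
Multi-group signatures are the union of all pairwise selections,
deduplicated and sorted — with three origin classes this is the
union-of-contrasts construction of the tumour subtype signature.

## Cell-type deconvolution

Reference profiles are the sorted cell types (alpha, beta, acinar,
duct, fibroblast, immune by default). Marker selection screens the
10,000 CpGs with the largest between-cell-type variance of type means
and keeps the top 500 by one-way ANOVA F across cell types (ties broken
by probe id; with a single replicate per type the ranking falls back to
the screening statistic). Each tumour is then projected onto the
reference means by the quadratic program

    minimize ||y - M w||^2   subject to   w >= 0,  sum(w) <= 1,

solved by SLSQP with analytic gradients (ftol 1e-14). The inequality
(rather than equality) constraint leaves room for an unexplained
tumour-intrinsic component. The coefficients times 100 are the percent
similarity to each cell type; samples are called alpha-like when alpha
similarity strictly exceeds 65%, beta-like analogously, otherwise
intermediate. Similarities are reported raw, not renormalized over
pancreatic types; a renormalization would change the threshold's
meaning and is left to the caller.

## Phyloepigenetic trees

Sample dissimilarity is 1 - Pearson correlation over a chosen CpG
subset (pairwise-complete under missingness; pairs sharing fewer than
30 probes are an error). Trees are built by Saitou-Nei neighbor
joining implemented from scratch: the pair minimizing
Q_ij = (n-2) D_ij - r_i - r_j is joined, ties broken by the
lexicographically smallest pair of subtree labels (smallest member tip
name) for determinism; branch lengths follow the canonical formulas
and negative lengths are retained but logged, so oracle comparisons
stay exact. Rooting places the root at the midpoint of the chosen
outgroup's pendant edge (an arbitrary beta reference in the pipeline).
Clade reading labels each tumour tip by the cell type of the nearest
reference tip in patristic distance, exact ties becoming "ambiguous";
this nearest-reference rule is one defensible formalization of "groups
with the normal cells" and is cross-checked against the 65% similarity
rule.

## Consensus clustering and k selection

Monti resampling consensus: for each k in 2..k_max and each of `reps`
iterations, floor(0.8 n) samples are drawn without replacement, the
1 - Pearson distance among them is clustered by Ward linkage on
squared dissimilarities (the "ward.D2" flavour; scipy's ward on a
precomputed dissimilarity implements the same update) and cut at k;
co-clustering counts conditional on co-sampling form the consensus
matrix. Final assignments cut an average-linkage tree of
1 - consensus. One seeded generator stream per k keeps runs
reproducible and independent of each other. When all features are used
(p_feature = 1) the pairwise distance matrix is computed once and
subset per draw — an exact optimization.

The number of clusters is chosen from the consensus CDF. The area
under the CDF of off-diagonal consensus values equals one minus the
mean consensus, so splitting *past* the true structure still inflates
the area: formerly certain co-assignments turn into intermediate
values. A pure delta-area elbow therefore over-selects. The selection
used here gates candidates by delta-area (relative gain > 0.025, the
documented elbow) and then takes the largest candidate whose consensus
matrix is still crisp — proportion of ambiguous entries (PAC, mass in
(0.1, 0.9)) at most 0.03. On planted-k fixtures PAC at the true k is
essentially zero and jumps an order of magnitude at the first
over-split, which is what makes this robust where the plain elbow is
not. A forced-k mode bypasses selection (used for the k = 2
TF-checkpoint analyses).

**TF-checkpoint probes.** The lineage transcription-factor checkpoints
(7 alpha: FEV, IRX2, LDB2, MAFB, PGR, PTGER3, BMP5; 9 beta: MAFA,
PDX1, SMAD9, CDKN1C, TFCP2L1, SIX3, SIX2, RFX6, MNX1) are pure
configuration and overridable. A probe qualifies when it is autosomal,
its chromatin state is one of the eight regulatory states (closed/
lowly-methylated/open weak enhancer, closed/open strong enhancer,
genic enhancer, insulator, polycomb repressed), and its nearest gene
is on the requested list. The counts such a filter yields on real
islet chromatin-state maps depend on that annotation and are not
built-in expectations.

## Copy-number inference

Per probe, log2(sample / median of reference samples), median-centred
per sample so whole-genome scaling cancels. Bins are built per
chromosome arm by a greedy left-to-right rule: a bin closes as soon as
it holds 15 probes, extension is capped at a 5 Mb span, and a closed
bin still short of 15 probes (a gap, or the arm's end) merges into its
left neighbour or is dropped if the arm has none. The nominal minimum
bin width (50 kb) documents the target granularity; with 450K-like
probe spacing 15 probes practically always exceed it. Arm values are
unweighted medians of bin medians plus an adjustable zero-threshold
offset (a knob meant to be recalibrated against orthogonal evidence
such as FISH; no FISH logic here), called gain/loss beyond +/-0.15. Arm profiles are
clustered by Ward/Euclidean into 3 groups by default, renumbered by
ascending mean |arm value| so group 1 has the fewest events.

## Survival

Kaplan-Meier product-limit estimation with Greenwood standard errors
and the multi-group log-rank test are delegated to lifelines; events
precede censorings at tied times (the conventional rule). The
package's own tests verify both against hand-worked product-limit
tables and a direct risk-set summation.

## Synthetic cohort

The generator emits the structure the analysis assumes, with defaults
mirroring a realistic PanNET cohort: 6 sorted cell types with 2 replicates
each (so the small-n moderated test is exercised); 20,000 probes of
which 5% are planted cell-type markers at |Δβ| = 0.35 and 2.5% sit on
X/Y to exercise filtering; 125 tumours in four groups — 19 alpha-like
(72% alpha weight), 14 beta-like (73% beta), 76 intermediate-ADM
(53/12 alpha/beta, MEN1/DAXX/ATRX-enriched) and 16 intermediate-WT
(51/14) — each group carrying a disjoint 150-CpG signature shifted by
1.5 logit units; three batches at logit shifts 0/+0.1/-0.1 assigned
round-robin so batch is not confounded with group; type II probes
compressed toward 0.5 with slope 0.8; arm-level intensity events
(chr11/6q/16p/22q/1p losses in ADM, 7p/17q gains in WT) at |log2|
0.3-0.35 on log-normal intensities; exponential relapse with
group-specific hazards (0.001-0.002/month for alpha/beta-like,
0.012-0.015 for the intermediates) under uniform censoring over 120
months.

Noise is Gaussian on the logit scale (sd 0.05) and back-transformed,
which keeps betas in [0, 1] without clipping. Each tumour additionally
perturbs its group's mixture weights log-normally (sigma 0.15) before
renormalization: ground truth records per-sample weights, and without
this heterogeneity the within-group samples are so exchangeable that
consensus clustering locks onto numerically tiny preprocessing
residuals as spurious stable splits. The jitter is kept small enough
that the 65% rule still recovers the planted origin labels.

What the generator does not emulate: probe-level measurement error
structure (spatial, dye, bead-count effects), SNP-affected probes,
correlated CpG blocks, tumour purity gradients within a sample,
copy-number influence on beta values, or non-exponential hazards.
Passing tests therefore demonstrate correctness of the algorithms
under the assumed generative model, not robustness to everything real
cohorts contain.

## Problem sizes and determinism

The bundled tests and the acceptance script run the pipeline at its
default cohort size (20,000 probes, 137 samples) with consensus
clustering at k_max = 10 and 250 resampling iterations — a quarter of
the conventional 1000, chosen because the consensus matrices of this
cohort stabilize well before that; the module default remains
k_max = 20, reps = 1000. Every source of randomness flows from a
single seed through per-stage substreams derived by CRC32 hashing of
the stage name, so adding a stage never shifts another's draws and a
rerun with the same seed is byte-identical.

## Known limitations

- The QP solver is SLSQP; for hundreds of cell types an active-set or
  interior-point solver would be preferable.
- Neighbor joining is O(n^3) with a dense matrix copy per join;
  adequate for hundreds of samples, not tens of thousands.
- ComBat's location/scale model does not capture batch-by-group
  interactions; the simulator's type II compression deliberately
  creates a small one, visible as a residual if BMIQ is skipped.
- Consensus clustering's k selection is a heuristic; the full
  delta-area and PAC profiles are always reported alongside the choice.
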
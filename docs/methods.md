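# Methods

This note documents the statistical model behind each stage, the tunable
parameters and their defaults, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the design was
genuinely open.

## Normalization and donor correction

Counts are normalized with **median-of-ratios size factors**: for every gene
with nonzero counts in all samples, the ratio of its count to its geometric
mean across samples is formed, and a sample's factor is the median of those
ratios. Genes with zero counts everywhere are dropped first (logged).

The variance-reducing transform is **log2(count/size_factor + 1)** with a
fixed pseudo-count of 1. A regularized log with gene-wise shrinkage would
track the mean-variance relation more closely at low counts, but every
downstream use of the transformed matrix here (marker shift tests,
heatmaps, diagnostics) is rank- or location-based and tolerates the simpler
transform; the pseudo-count mainly matters below ~5 counts, where the
expression filter already removes genes from testing.

**Donor centering** replaces, per gene, each donor's mean with the grand
mean. Between-individual composition differences dominate sample clustering
in whole blood, and with only two samples per donor a scale (variance)
adjustment per donor cannot be estimated stably, so the correction is
location-only. Centering preserves every within-donor after-minus-before
difference, which is exactly the quantity all paired contrasts use.
Empirical-Bayes batch adjustment with scale shrinkage is deliberately out
of scope.

## Paired differential expression

Per gene, the per-donor paired log fold changes
`d_i = log2(after_i/sf + 1) − log2(before_i/sf + 1)` are summarized by their
mean (the reported log2FC) and tested with a two-sided one-sample t
statistic. With n = 7 pairs the per-gene variance is noisy, so it is
**moderated**: shrunk toward a prior with weight equivalent to
`prior_df = 3` extra degrees of freedom,

    s²_post = (d0·s²_prior + (n−1)·s²_gene) / (d0 + n − 1),   df = d0 + n − 1.

The prior follows the **mean-variance trend**: genes are split into up to 20
equal-occupancy bins of mean log expression and the prior for a gene is the
10%-trimmed mean variance of its bin. A single global prior would be
dominated by noisy low-count genes and systematically inflate the variance
of well-measured genes — precisely the genes a blood signature is built
from — so the trend-aware prior is used instead. Moderation can be disabled
(`moderate=False`), in which case the statistic is the textbook paired t
with df = n − 1.

Genes with mean normalized count < 1 are excluded from testing (flagged,
not silently dropped): an explicit, transparent analogue of the independent
filtering that count-based DE frameworks perform internally. Zero-variance
genes receive p = 1 when the mean difference is also zero. Multiplicity is
controlled with Benjamini–Hochberg FDR over the tested genes; DEGs are
called at FDR < `alpha` (default 0.1, the convention for this design).
`mean_tpm` is computed from gene lengths when present, otherwise
counts-per-million are reported (logged).

Reported summaries follow the field's reporting conventions for this
design: DEG counts stratified by mean-TPM cutoffs (0/10/100), and
"strong" DEGs defined as changing strictly more than twofold
(|log2FC| > 1; the boundary itself is excluded).

## Marker derivation

"Most discriminating" is operationalized as the **one-vs-rest Wilcoxon
rank-sum AUC** on normalized expression (counts scaled to 10,000 per cell,
then log2(x+1)), the de-facto standard in single-cell marker ranking; the
log2 ratio of mean counts and the detection-fraction difference are carried
along as secondary scores. Clustering is out of scope — cell labels are
taken as input.

Every gene is assigned **uniquely** to its argmax-AUC type (ties: larger
log2FC, then lexicographic), because the downstream shift and enrichment
logic treats markers as cell-type-exclusive. Within a type, markers are
ranked by AUC and truncated to `max_markers = 20`; genes below
`auc_min = 0.7` are dropped so weak markers cannot dilute the shift tests.
Types may legitimately end up with fewer than 20 markers (warning).

## Marker-proxy composition shifts

A change in a cell type's abundance moves the bulk expression of its
markers coherently, so marker expression serves as a proxy for the
*relative* population change; no deconvolution to absolute fractions is
attempted. For each type the donor-corrected log expression of its markers
is first centered per marker (markers differ by orders of magnitude in
absolute level), then the per-marker per-donor after-minus-before
differences (20 markers × 7 donors = 140 values) are tested with a
two-sided **Wilcoxon signed-rank** test.

The observational unit deserves a note. Pooling the marker × sample values
of the two conditions and running an unpaired rank-sum test looks natural,
but with exactly two samples per donor, donor centering makes the before
and after pools exact mirror images of each other (`x_before = −x_after`
per gene per donor). The unpaired test's independence assumption then fails
and it becomes anticonservative — unchanged cell types acquire spurious
stars. The signed-rank test on the paired differences uses the same pooled
information while respecting the pairing, and at these sample sizes still
resolves the true shifts at p < 0.001. The pooled unpaired variant remains
available (`variant="pooled_unpaired"`; exact enumeration for pooled group
sizes ≤ 8, normal approximation with tie correction above).

Direction is the sign of the mean difference when p < 0.05, else
`no_change`; star notation is `***` p<0.001, `**` p<0.01, `*` p<0.05, `-`
otherwise. No correction is applied across the 12 cell types (raw stars are
the reporting convention here; stated in the output header). Types with
fewer than 5 markers present in the bulk matrix are reported flagged rather
than dropped.

## Gene-set enrichment

**ORA** is a one-sided Fisher exact test per set on the 2×2 table of set
membership × query membership within the tested universe (sets intersected
with the universe first), BH-corrected across the collection. The Fisher
helper reports the sample odds ratio a·d/(b·c) (∞ or undefined flagged
explicitly) with the conditional hypergeometric p.

**GSEA** is the classic weighted running-sum statistic: genes ranked by
`sign(log2FC) · (−log10 p)` by default (`log2fc` available as an
alternative ranking), hits increment by |score|^weight normalized over the
set's hits, misses decrement by 1/(N − n), and the enrichment score is the
maximum deviation from zero. Significance comes from **gene-label
permutation** (the 7-pair design offers far too few sample permutations),
one-sided within the sign of the observed ES with a +1 smoothing term; NES
divides ES by the mean same-sign null |ES|. The leading edge is the set
members at or before the extremum (after it for negative ES). Default
`n_perm = 10000` for standalone use; the orchestrated pipeline default is
1000 to keep full runs fast, and the value is recorded in the output
header. Adaptive multilevel p-value refinement is out of scope.

## Cross-study specificity

A DEG is "previously seen" if **any** external dataset reports it at
unadjusted p < 0.05 — direction is deliberately ignored (the conservative
reading), and the threshold is configurable since it is a convention, not a
derived quantity. Removal is attributed per dataset. Per cell type, marker
enrichment among the unique DEGs is a one-sided Fisher exact test on
{unique, previously-seen} × {marker, non-marker}, BH across the 12 types.
The signature keeps unique DEGs with mean TPM ≥ 10 and |log2FC| ≥ 0.5
(both inclusive), annotated by marker cell type and sorted by cell type
then decreasing log2FC.

For external datasets that exist as expression matrices rather than DE
tables, `microarray_paired_de` provides a donor-paired t test on
log-intensity values, so the full loop (re-analysis → DE table → filter)
runs on synthetic data. Duplicate probes/genes in supplied DE tables are
collapsed to the minimum p — conservative for a filter that removes on
significance. Excluding an outlier dataset is a manual configuration
decision (as it is visual/diagnostic in practice), not automated.

## Synthetic data generator

The generator emulates the design of a paired altitude-exercise whole-blood
study: 7 donors × {before, after}, 12 blood cell types, and a panel of 7
external comparison datasets.

**Single-cell reference.** A shared log-normal base profile (σ = 1) with
small per-type jitter (σ = 0.1) makes background genes uninformative; each
type's 30 planted markers are elevated 32-fold in their own type on a
3-fold-raised baseline (canonical lineage markers are specific *and*
well-expressed transcripts). Cells draw negative-binomial counts
(dispersion 0.3) around their type profile at ~2,000 counts/cell, 200 cells
per type.

**Bulk cohort.** Bulk expectation is the mixture Σ_t fraction_t ×
profile_t. Baseline fractions are **mRNA contribution** fractions, not cell
counts: lymphocytes are RNA-rich while neutrophils (and the anucleate
platelets and erythrocytes) contribute less mRNA per cell than their counts
suggest, so the lymphoid pool carries substantial weight (defaults in
`BASELINE_MRNA_FRACTIONS`, summing to 1). Donor individuality enters twice:
per-donor log-normal perturbation of the composition (CV 15%) and log-normal
expression offsets on 10% of genes per donor (σ = 0.5), shared by both of a
donor's samples — together these reproduce the donor-dominant clustering
structure of real blood. Within-donor sampling jitter on the composition is
small (CV 1%): the paired draws are same-morning samples, and types the
condition does not move should be genuinely unmoved.

The default condition shift (`SHIFT_PATTERNS["altitude"]`) raises
neutrophils ×1.6, CD14+ monocytes ×1.3, erythrocytes and platelets ×1.35,
lowers CD4 memory T ×0.60, CD8 T and NK ×0.55, B ×0.75, pDC ×0.60, and
leaves naive CD4 T, CD16+ monocytes and mDC unchanged — magnitudes in the
range reported for acute strenuous exercise (tens of percent). Fractions
are renormalized per sample, so "unchanged" is relative: the shifted
pattern nets out close to total-neutral, as it must for relative
expression data to show stable types as stable.

Direct condition effects are planted on 50 "altitude-specific" plus 60
"shared" non-marker genes with |log2FC| drawn uniformly in [1, 2] (random
sign), applied only to after samples and independent of composition.
Planted genes receive baseline expression typical of established blood
biomarkers (target ~50 normalized counts, log-normal spread): low-abundance
transcripts are not plausible signature candidates, and at a 7-pair design
they would be undetectable regardless of effect size. Counts are negative
binomial with dispersion 0.05 (typical bulk RNA-seq); library sizes are
log-uniform in [12,400, 40,800] — the 12.4–40.8M read-depth range of a
typical whole-blood experiment scaled down 1,000× so that simulations run
in seconds; gene lengths are uniform in [500, 5000] bp.

**External tables.** Each of the 7 tables covers the full gene universe
with uniform background p-values (~5% spuriously significant, as in any
real study); each table independently flags a random 60%
(`overlap_fraction`) of the shared planted genes at p < 0.05, so the union
over 7 tables removes >99% of them; altitude-specific planted genes always
receive p ≥ 0.1, mimicking responses genuinely absent from prior studies.

**What passing tests do and do not show.** The generator produces clean
mixtures: no batch or lane effects, no globin carryover, no gene-gene
correlation beyond composition, no probe-mapping noise in the external
tables, and marker genes that are perfectly cell-type-exclusive by
construction. Recovery results on it demonstrate the pipeline's logic and
calibration, not its performance on real whole-blood data, where marker
promiscuity and technical structure will blur all of these margins.

## Problem sizes and numerical choices

Simulated checks use 5,000-gene references for composition/marker/filter
properties and 10,000-gene cohorts for DE sensitivity and null calibration;
20 seeded cohorts for shift-direction recovery, 50 for DE recovery, 10 for
the specificity filter. GSEA null calibration uses 200 random sets over a
1,000-gene ranking at 500 permutations. These sizes give stable averages
while keeping any single check in seconds.

Determinism: all randomness flows through `numpy.random.default_rng` seeds;
an orchestrated run writes no timestamps into its outputs, so re-running
with the same seed and paths is byte-identical (the free-form run log is
the one exception and is excluded from comparisons). Ties in rankings are
broken lexicographically by gene ID throughout, which makes marker
catalogs, rankings and leading edges independent of input order.

## Known limitations

- The paired moderated t on log ratios is not a negative-binomial
  likelihood test; at very low counts it loses power relative to
  count-model Wald/LRT tests, and DEG counts on real data will differ from
  analyses using those.
- Location-only donor centering ignores donor-specific variance; a donor
  with systematically noisier samples is not down-weighted.
- Marker-proxy shift inference reports relative direction and confidence,
  not effect size in cell-fraction units; strongly correlated composition
  changes between types are not disentangled.
- The uniqueness filter is presence/absence of significance; it does not
  pool effect sizes across studies and inherits any multiplicity choices
  the external tables made upstream.
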
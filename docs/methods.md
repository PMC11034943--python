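# Methods

This note records the models, parameter choices and numerical conventions
behind `epiclone`, and what the synthetic study conditions do and do not
establish about real data.

## Mutation dynamics and clonal bins

A mutation with variant allele frequencies (VAF) at both timepoints is
**gained** iff `vaf_dx < 0.05 and vaf_rel > 0.1`, **lost** iff
`vaf_dx > 0.1 and vaf_rel < 0.05`, otherwise **stable**. Both inequalities
are strict: a VAF of exactly 0.05 or 0.1 can never trigger a gain or loss.
Non-quantifiable events (FLT3-ITD, NPM1 insertions) are classified from
absent/present calls instead. A consequence of the rule as written, which we
follow, is that a mutation absent at diagnosis with a relapse VAF in
(0.05, 0.1] is stable — the gain condition's upper threshold is simply not
met.

Patients are binned from their mutation classes: Stable (no gained, no
lost), Gain, Loss, GainAndLoss; *clonality* is stable only for the Stable
bin, so "unstable" means any change at relapse. Before binning, Tier 3
variants (synonymous / unknown significance) are dropped, and a patient is
evaluable only if every remaining variant carries both timepoint values.
Targeted-panel input additionally passes a major-clone filter (average
VAF > 5% at either timepoint); variants with no tier annotation are treated
as Tier 3 and logged.

Survival: Kaplan–Meier curves and the log-rank test compare stable vs
unstable clonality on relapse-free time; the adjusted analysis is a Cox
proportional-hazards model `h(t) = h0(t)·exp(β1·stable + β2·age + β3·male)`
fit with lifelines using the Efron approximation for ties (the tie-handling
choice is ours; nothing in the analysis depends on it at these sample
sizes). Patients missing age or sex are dropped from the adjusted model
with a warning. The reported hazard ratio is `exp(β1)`.

## Bulk chromatin accessibility

**Cut sites.** Each fragment contributes insertions at `start + 4` and
`end − 5` (0-based half-open coordinates throughout). The +4/−5 pair is the
convention that centers the Tn5 insertion offset of 9 bp.

**Consensus peaks.** Per-sample fixed-width (500 bp) peak calls are merged
by iterative removal: sort by descending significance score (ties broken by
chromosome and start for determinism), repeatedly keep the best remaining
peak and discard everything overlapping it. Blacklisted peaks are removed
before merging. A retained peak must be overlapped by calls from ≥ 2
distinct biological samples; we count biological samples, not technical
replicates. The result is pairwise disjoint by construction.

**Similarity.** Columns are CPM-normalized, technical replicates averaged
per (patient, timepoint), and the diagnosis–relapse Pearson correlation is
taken across all peaks. The same routine serves LSC vs non-LSC
comparisons.

**Differential accessibility** uses the DESeq2 negative-binomial GLM
(pydeseq2): median-of-ratios size factors, per-feature dispersion with
trended empirical-Bayes shrinkage, and a Wald test on the timepoint
coefficient in the design `~ patient + timepoint`, i.e. patient identity as
a fixed-effect covariate absorbing between-patient baseline differences.
P values are Benjamini–Hochberg adjusted; all-zero features are excluded
and reported as NA. On a 2,000-feature null cohort (10 patients × 2
timepoints, the simulator's default noise) the empirical type-I error at
α = 0.05 is measured by the acceptance suite and falls within [0.03, 0.07].

**Locus window scan.** Sliding 100-kb windows at 50-kb steps (a scale
chosen to resolve ~100-kb co-regulated blocks); each window with ≥ 5 peaks
is scored by a binomial tail test of its count of significantly
enriched (or depleted) peaks against the genome-wide significant fraction,
then BH-adjusted. The window test is a declared stand-in for a locus-level
enrichment scan; its defaults are package choices, not inherited values.

**Motif enrichment** takes precomputed peak×motif annotations (PWM scanning
is out of scope) and reports hypergeometric tail probabilities in both the
enrichment and depletion directions, an odds ratio (infinite when the
foreground captures all motif-positive peaks with no negatives), and BH
adjustment.

## Gene accessibility scores and GSEA

Counts on 5-kb genomic tiles are depth-normalized per sample to 10⁴ total
insertions (the normalization constant is a package choice; scores are
invariant to joint rescaling of counts and depth). For each gene the
extended body spans [TSS − 5 kb, TTS] strand-aware. Tile weights:

- overlapping the extended body: `1 + e⁻¹`;
- flanking, at interval distance `d` from the body: `e^(−d/5000) + e⁻¹`
  (measured from the nearest edges of the span and the tile, making the
  weight continuous — `d = 0` reproduces the body weight);
- zero when `d > 20,000` or the tile overlaps another gene's extended body.

The gene score is the weighted sum over its tiles, a chromatin proxy for
expression.

The **relapse signature** ranks genes by the relapse-vs-diagnosis
differential statistic (log2 fold change by default) computed on clonally
stable patients and takes the top and bottom 500; with fewer than 1,000
genes it splits evenly and never overlaps. The per-cell **relapse
chromatin score** is Σ(top-gene scores) − Σ(bottom-gene scores); missing
signature genes contribute 0 and are logged.

**Pre-ranked GSEA** uses the weighted Kolmogorov–Smirnov running sum with
weight exponent 1: member genes add `|s_g| / Σ_set|s|`, non-members
subtract `1/(N − k)`; the enrichment score (ES) is the maximum signed
deviation. Ranking ties break by gene name for determinism. The null is
gene-label permutation: random same-size sets, with the p value taken in
the same-signed tail and NES = ES / mean |null ES| of that sign. A set
spanning the whole ranking scores 0 by construction. Sets with fewer than
5 ranked members are skipped. The permutation seed is a required parameter.

## Projection to a healthy reference

Latent semantic indexing: binarize the cell×peak matrix, row-normalize to a
constant (10⁴), weight by `idf = log(1 + N_cells / feature_frequency)`, and
take a truncated SVD. Embeddings are `X·V`, so projecting the training
matrix reproduces the training embedding exactly, and query cells — with
features mapped onto the model's feature set, missing ones zero-filled —
use the *reference* IDF and singular vectors with no refitting. Because of
the row normalization the embedding is depth-invariant. The first component
is dropped when its |correlation| with log depth exceeds 0.75 (it then
encodes sequencing depth); 25 components are retained by default, one
single LSI pass (the iterative variant is a possible extension). Component
signs are fixed deterministically.

Bulk samples enter single-cell space as **pseudo-single cells**: 250 cells
per sample by default, each drawing 10,000 cut sites uniformly without
replacement from the bulk pool (the per-cell read count is a package
default; the aggregate of the pseudo-cells converges to the bulk CPM
profile). **Closest-normal** labels come from a k = 10 Euclidean nearest-
neighbor vote in LSI space; label ties resolve to the smaller mean
distance.

## Single-cell analysis

Cells pass QC on total fragments, fraction of fragments in peaks and an
externally supplied doublet flag (doublet scoring itself is upstream of
this package). Clustering builds a k = 20 shared-nearest-neighbor graph
with Jaccard edge weights and optimizes modularity (Leiden,
RBConfiguration) at a user resolution with a fixed seed.

Residual healthy immune cells are removed as whole clusters only when two
criteria hold simultaneously: the cluster's mean accessibility over a
marker panel (default: the T/B/monocyte panel CD89, TLR4, GZMA, CD247,
TCL1, CD37, CD209) exceeds the across-cluster mean by z ≥ 2, *and* the
cluster is epigenetically dissimilar to the rest of the sample (mean
pseudobulk correlation below a cutoff, default the 5th percentile of
inter-cluster correlations). This two-criterion rule is our formalization
of a qualitative curation step. As a safety invariant the filter refuses to
remove more than half the cells unless forced.

Cluster pseudobulks are summed counts, CPM-normalized; their pairwise
Pearson matrix (symmetric, unit diagonal) plus an average-linkage grouping
identifies diagnosis clusters that group with relapse clusters.

## Mitochondrial clone tracing

Per-variant, per-cell heteroplasmy is `alt/(alt + ref)`, missing when the
cell has no coverage. Variant QC keeps a variant iff it is detected in
> 3 cells, its strand correlation (Pearson correlation of per-cell alt
counts between strands, over cells with reads on both strands) is > 0.65,
and mean coverage is > 10 reads — all strict inequalities. Technical
artifact variants put their alternate reads on one strand per cell and are
removed by the strand criterion.

Clustering binarizes heteroplasmy at ≥ 0.1 (a package default; the matrix
is then a cell barcode) and applies the SNN/modularity procedure. The
clustering resolution is deliberately a user parameter with a sweep helper
(`sweep_resolution`, reporting clone counts and silhouettes), because no
single resolution suits all clonal structures. Micro-clusters below 1% of
cells are dissolved into the nearest major cluster by binary-profile
distance: at realistic coverage a fraction of cells has zero reads at a
variant, and such dropout cells otherwise form spurious clusters that lack
an ancestral variant and corrupt the tree. Per-cluster mean heteroplasmy
is computed over covered cells only, and clusters whose top defining
variant averages < 0.1 are flagged as driven by low-heteroplasmy variants.

The clone tree is reconstructed from containment: a variant is present in
a clone at mean heteroplasmy ≥ 0.2 (default); variants present in all
clones form the root edge; each clone's parent is the clone with the
largest strict subset of its variants. Ambiguous parents and non-nesting
overlaps (shared variants not explained by the deepest observed common
ancestor or the root set) are reported as conflicts and can be resolved
with a manual override table, mirroring the manual curation such
hierarchies receive in practice.

Clone frequencies per timepoint are compared clone-by-clone with a
two-proportion z test with continuity correction (the package's choice of
test for expansion/contraction). **Convergence** is tested by collecting
all within-timepoint inter-clone pseudobulk correlations at diagnosis and
at relapse and comparing the two collections with an unpaired Welch t test;
convergent epigenetic evolution is declared when the relapse mean exceeds
the diagnosis mean at p < 0.05. **Shift concordance** correlates clones'
per-feature `log2((CPM_rel + 1)/(CPM_dx + 1))` vectors; a high correlation
between clones of distinct origin indicates a shared relapse program.

## Synthetic study conditions

The generators are pure functions of (config, seed) and always return the
planted truth separately from the data; recovery tests consume only the
data.

- **Mutation cohort** — 216 patients by default with bin probabilities
  (0.43, 0.20, 0.17, 0.20); 1–8 mutations per patient whose VAF draws force
  the planted class (gained: dx ∈ [0, 0.045], rel ∈ [0.12, 0.5]; lost
  mirrored; stable: both ≥ 0.105); ~10% of FLT3/NPM1 events are
  non-quantifiable presence calls. Clinical covariates: age ~ N(60, 10)
  truncated to [18, 90], sex Bernoulli(0.5), relapse times exponential with
  the stable-bin hazard 1.56× the unstable hazard (scale 400 days), 15%
  uniform censoring — so the survival stage has a planted effect of
  realistic size to recover.
- **Bulk cohort** — lognormal per-peak baselines (default mean 30 counts)
  times a lognormal patient factor, negative-binomial noise (dispersion
  0.1 — typical of ATAC replicates), two technical replicates per sample;
  the first `signature_size` peaks are shifted by `effect_log2fc` at
  relapse. The default universe is 20,000 peaks with a 500-peak signature —
  a deliberately scaled-down peak universe that keeps the differential
  stage's run time in minutes while preserving its multiplicity structure.
- **Healthy reference** — four hematopoietic-like types (HSC → Progenitor →
  Myeloid/Lymphoid); each type adds a private block of enriched peaks to
  shared housekeeping accessibility and inherits ancestral blocks at
  decaying strength, so parents sit between their children; per-cell counts
  are multinomial at Poisson depth.
- **Mitochondrial scATAC** — cells drawn from a clone tree with
  per-timepoint frequencies; alt reads Binomial(coverage, heteroplasmy
  0.9 by default) with binomial strand splitting. Per-cell coverage is
  negative-binomial (mean 20, dispersion 0.5) rather than Poisson: with
  Poisson coverage, binomial thinning makes the two strands exactly
  independent for a variant at uniform heteroplasmy, and the > 0.65
  strand-correlation heuristic would then reject true clone variants. The
  overdispersed depth that real libraries exhibit is precisely what makes
  strand concordance informative. Artifact variants place all alt reads on
  a single strand per cell. Clone chromatin programs add private peak
  blocks; convergence mode pulls every clone's relapse program toward one
  shared profile with weight 0.8.

**What passing does and does not show.** The synthetic conditions plant
clean block structure, independent noise and exactly inherited variants;
real cohorts add copy-number aberrations, batch effects, doublets,
ambient contamination, mapping artifacts and clonal admixture that the
generators do not emulate. Green recovery tests therefore establish the
correctness and calibration of the implementations under their stated
models, not their robustness to every failure mode of real libraries. The
published-cohort check (patient counts, WT1 gain rate, hazard ratio) runs
only when the collated meta-analysis tables are supplied under `data/`.

## Numerical conventions

Coordinates are 0-based half-open everywhere; counting uses
`[start, end)`. CPM columns sum to 10⁶. Degenerate inputs raise rather
than return silently: zero-variance correlation inputs, all-censored
survival groups, empty differential sets, zero-depth samples and
zero-count clusters are all signalled. All stochastic routines take
explicit seeds and are covered by determinism tests.

## Problem sizes

The test suite and the acceptance script run everything at desk scale on
one CPU: 216–600 patients for the survival stage, 2,000-feature null and
20,000-feature power cohorts for the differential stage, 1,500–2,000-peak
references with 240–400 cells for projection, 3–12-clone trees with
1,000–3,000 cells per timepoint for clone tracing, and 2 × 50 seeds for
convergence power/calibration. These sizes were chosen as the smallest at
which the statistical claims under test (CI coverage, ≥ 80% recovery,
≥ 90% power) are meaningful.
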
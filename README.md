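# epiclone

Genetic and epigenetic clonal-evolution analysis for relapsed acute myeloid
leukemia (AML), built around paired diagnosis/relapse samples.

A substantial fraction of AML patients relapse without any change in their
driver mutations. `epiclone` implements the analysis stages needed to ask
whether such clonally *stable* relapses are driven by epigenetic rather than
genetic evolution:

1. **Clonal evolution from VAFs** (`epiclone.clonal_evolution`) — each
   mutation with variant allele frequencies (VAF) at diagnosis and relapse is
   classified *gained* (VAF < 0.05 → > 0.1), *lost* (VAF > 0.1 → < 0.05) or
   *stable*; patients are binned Stable / Gain / Loss / Gain+Loss, and
   relapse-free survival of stable vs unstable clonality is compared by
   Kaplan–Meier/log-rank and an age- and sex-adjusted Cox model
   (HR = exp(β_stable), Efron ties).
2. **Bulk chromatin accessibility** (`epiclone.bulk_chromatin`) — Tn5 cut
   sites (fragment start +4 / end −5), iterative-removal consensus peak sets
   of fixed 500-bp peaks, per-patient diagnosis–relapse Pearson similarity of
   replicate-averaged CPM profiles, and relapse-vs-diagnosis differential
   accessibility with a negative-binomial GLM (DESeq2 model; patient fixed
   effects, Wald test, Benjamini–Hochberg), plus locus window scans, overlap
   fractions and hypergeometric motif enrichment.
3. **Gene accessibility scores and GSEA** (`epiclone.gene_scores`) — 5-kb
   tile counts weighted by an exponential distance decay
   (weight = 1 + e⁻¹ in the extended gene body [TSS−5 kb, TTS];
   e^(−|d|/5000) + e⁻¹ on flanks; 0 beyond 20 kb or inside a neighboring
   gene), summed per gene; top/bottom-500 relapse signatures and pre-ranked
   GSEA with a weighted Kolmogorov–Smirnov running sum and a gene-label
   permutation null.
4. **Projection to a healthy hematopoietic reference**
   (`epiclone.projection`) — TF-IDF + truncated SVD (latent semantic
   indexing) fitted on a healthy single-cell reference; bulk samples enter
   as 250 pseudo-single cells subsampled from their cut-site pool; queries
   are projected with the *reference* IDF and singular vectors and labeled
   by 10-nearest-neighbor vote ("closest normal" cell type).
5. **Single-cell ATAC and mitochondrial clone tracing**
   (`epiclone.single_cell`, `epiclone.mitoclones`) — SNN/modularity
   clustering, contaminant-cluster removal, per-cell relapse chromatin
   scores (Σ top-signature gene scores − Σ bottom), mitochondrial variant QC
   (> 3 cells, strand correlation > 0.65, coverage > 10), heteroplasmy
   clustering into "mitoclones", containment clone trees, clone-frequency
   expansion tests, and the convergent-evolution test: unpaired t-test
   comparing inter-clone pseudobulk correlations at relapse vs diagnosis.

`epiclone.synthetic_data` generates every input with planted ground truth
(clonal VAF dynamics, negative-binomial peak counts with a planted relapse
signature, a cell-type-structured reference, mitochondrial allele counts
drawn from a clone tree), so the entire pipeline runs and is tested without
any external data.

## Worked example

```python
from epiclone import clonal_evolution as ce, synthetic_data as sd

cfg = sd.SimConfig(seed=1, n_patients=216)
mutations, clinical, truth = sd.simulate_mutation_cohort(cfg)

evaluable  = ce.filter_evaluable_patients(mutations)
classified = ce.classify_mutations(evaluable)
bins       = ce.bin_patients(classified)
surv       = ce.survival_compare(bins, clinical)

print(bins["bin"].value_counts(normalize=True).round(3).to_dict())
print(f"Cox HR (stable vs unstable) = {surv['cox_hr']:.2f}, p = {surv['cox_p']:.4f}")
```

prints

```
{'Stable': 0.426, 'GainAndLoss': 0.213, 'Gain': 0.199, 'Loss': 0.162}
Cox HR (stable vs unstable) = 1.66, p = 0.0010
```

i.e. ~43% of the simulated cohort relapses with an unchanged mutation
profile, and clonally stable patients relapse faster (hazard ratio above 1;
the generator plants a true HR of 1.56, and the estimate fluctuates around
it with the sampling error expected at n = 216).

The same pattern holds for the other stages: `bulk_chromatin` recovers the
planted relapse-shifted peaks, `projection` re-labels held-out synthetic
cells with their true cell type, and `mitoclones` reconstructs planted clone
trees and flags a planted 0.2% → 36% clone outgrowth as significant.
The command-line entry point `epiclone clonal --mutations M.tsv --clinical
C.tsv --out DIR` runs stage 1 on user tables; `epiclone simulate --out DIR`
writes a synthetic fixture bundle.

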
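# scmetaboscape

Single-cell metabolic landscape analysis for tumor transcriptomics:
cell-type metabolic pathway activity scoring with a permutation null,
per-cell GSVA-style pathway enrichment, discovery of high/low metabolic
subclusters among malignant cells, marker-signature extraction, and
signature-based survival stratification of a bulk cohort — together with a
synthetic-data generator that plants recoverable ground truth for every
stage.

## Who this is for

Tumor scRNA-seq studies increasingly ask not *which* cell types are present
but *how metabolically active* each one is: malignant epithelial cells
reprogram KEGG metabolic pathways (oxidative phosphorylation, nucleotide
and amino-acid metabolism), and the degree of reprogramming stratifies
patients. This package implements that analysis chain as a tested,
reusable library. Because the real cohorts behind such studies are large
downloads with no ground truth, every stage here is validated on simulated
data where the planted effect sizes, cluster labels, dropout masks, size
factors and hazard ratios are known and recovery can be measured.

## The statistics at the core

**Pathway activity per cell type.** For gene $g$ and cell type $t$, the
relative expression is

$$r_{gt} = \frac{\bar{x}_{gt}}{\tfrac{1}{T}\sum_{t'} \bar{x}_{gt'}}$$

(1 = parity across types). A pathway $P$ scores

$$S_{tP} = \frac{\sum_{g \in P} w_g\, r_{gt}}{\sum_{g \in P} w_g},
\qquad w_g = \frac{1}{\#\{\text{pathways containing } g\}},$$

after excluding outlier genes ($\max_t r_{gt} > Q_3 + 3\,\mathrm{IQR}$ of
the pathway's pooled $r$ values). Significance: cell-type labels are
permuted across cells and the entire statistic recomputed;
$p = (1 + \#\{|S^{\text{perm}} - 1| \ge |S^{\text{obs}} - 1|\})/(1 + B)$,
Benjamini–Hochberg adjusted across all (pathway, type) entries.

**Per-cell enrichment (GSVA).** Per gene, a kernel-smoothed cumulative
density statistic across cells (Gaussian kernel, bandwidth $s_g/4$); per
cell, genes are ranked and a weighted Kolmogorov–Smirnov random walk over
the ranked list yields one score per (pathway, cell). Malignant cells are
then split by complete-linkage hierarchical clustering (Euclidean distance
on per-pathway z-scored scores, tree cut at $k=2$), and clusters are named
"high"/"low" from their mean scores.

**Survival.** A bulk cohort is scored per sample with the same GSVA
machinery on a marker signature; the optimal score cutpoint maximizes the
standardized two-group log-rank statistic over all admissible splits
(maximally selected rank statistic, `minprop` 0.1); groups are compared
with Kaplan–Meier/log-rank and a multivariate Cox proportional-hazards
model (Efron ties). Because a maximally selected statistic inflates the
naive log-rank p-value, a permutation-based selection-adjusted p is also
reported.

Supporting stages: QC filtering (≥500 genes, ≥1000 UMIs, ≤20%
mitochondrial), dropout imputation via a per-gene zero-anchored mixture
model with similar-cell non-negative regression, and four size-factor
estimators (pooled deconvolution, RLE, TMM, upper-quartile).

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from scmetaboscape import clustering, enrichment, preprocess, simulate

cfg = simulate.SimulationConfig(
    n_genes=600, n_cells=700, n_cell_types=1, n_pathways=15,
    genes_per_pathway=20, planted_split_fraction=0.5,
    planted_split_boost=3.0, seed=3,
)
expr, truth = simulate.simulate_dataset(cfg)
factors = preprocess.size_factors(expr, method="deconvolution")
lognorm = preprocess.normalize(expr, factors, log_transform=True)
scores = enrichment.gsva_scores(lognorm, truth.pathways)
named = clustering.label_high_low(clustering.hierarchical_split(scores), scores)
print(named.labels.value_counts().to_dict())
print(adjusted_rand_score(truth.true_metabolic_group.values, named.labels.values))
```

prints

```
{'low': 355, 'high': 345}
0.9380419922688754
```

— the 350/350 planted high/low split is recovered with adjusted Rand index
0.94. The `examples/` directory has one short script per capability
(simulation, pathway activity, metabolic clustering, markers/signatures,
survival, imputation/normalization); each prints the numbers it computes
and what they mean. A full pipeline run is one call
(`scmetaboscape run --out DIR --seed 1`, or `pipeline.run(PipelineConfig())`
from Python) and writes per-stage TSVs plus a manifest with content hashes;
re-running the same config reproduces the outputs byte-for-byte.

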
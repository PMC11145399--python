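# Methods

This note documents the models and procedures implemented in
`scmetaboscape`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Synthetic data model

`simulate.simulate_counts` draws UMI-like counts per gene $g$ and cell $c$
from a negative binomial with mean

$$\mu_{gc} = b_g \cdot m_{g,\,t(c)} \cdot s_c$$

where $b_g \sim \Gamma(\text{shape}, \text{scale})$ is the gene's base
expression (defaults 0.5, 2.0 — a long-tailed profile with many
low-expressed genes), $m_{g,t}$ is the activity multiplier the gene
inherits from its pathways (the largest fold factor among containing
pathways; 1 when none is planted), and $s_c \sim \mathrm{LogNormal}(\mu,
\sigma)$ is the cell's size factor, rescaled to geometric mean 1
(default $\sigma = 0.35$, a typical droplet library-size spread).
Gene-level NB dispersions are log-normal (default $\mathrm{LogNormal}(0,
0.5)$, i.e. dispersion ≈ 1 — strong UMI-scale overdispersion).

Technical dropout zeroes each positive count with logistic probability
$1/(1 + e^{\beta(\log(1+\mu_{gc}) - m_0)})$ — *decreasing* in the latent
mean (midpoint $m_0 = 1.0$, slope $\beta = 1.5$ by default), which is the
mean–dropout relationship the imputation stage assumes. The boolean
dropout mask, the latent means and the pre-dropout counts are all kept in
`GroundTruth`, so recovery can be measured exactly. A `dropout=False`
switch produces dropout-free data for scenarios that require it
(size-factor recovery, dropout-model type-I checks).

Pathway gene sets are built with controlled overlap (default 20% of each
pathway's genes re-drawn from earlier pathways) so the 1/multiplicity
weights in pathway scoring are exercised nontrivially.

`plant_metabolic_split` multiplies the latent means of all pathway genes
by a boost factor in a random fraction of the malignant cells and re-draws
their counts; defaults (fraction 0.5, boost 3) give a split that per-cell
pathway scoring should recover nearly perfectly, while boost 1 is the null
case. These effect sizes are a testability choice — there is no published
effect-size estimate for such splits — and are deliberately not tuned
beyond that choice.

`simulate_bulk_survival` drives a step-hazard model: a latent standard
normal score per sample shifts the (log) expression of the signature
genes, and event times are exponential with hazard $h_0 \cdot
\mathrm{HR}^{\,[score > cut]} \cdot e^{\beta^\top z}$, with independent
exponential censoring calibrated to the requested censored fraction.

**What the generator does not emulate:** ambient RNA, doublets, batch
effects beyond the sample label, gene–gene correlation beyond the planted
pathway structure, cell-cycle or other nuisance programs, and empirical
count distributions of any real dataset. Passing tests therefore show that
each algorithm recovers what it is designed to recover under its stated
model — not that the pipeline is robust to every artifact of real droplet
data.

## Quality control

Cells are kept when detected genes ≥ `min_genes` (500), total UMIs ≥
`min_umis` (1000) and mitochondrial fraction ≤ `max_mito_fraction` (0.20),
identified by gene-id prefix (default `MT-`). All three boundaries are
inclusive — the convention had to be fixed somewhere, and inclusive
thresholds keep a cell that sits exactly on a published cut. Filtering is
idempotent.

## Dropout model and imputation

Within each sample, each gene's $\log(\mathrm{TPM}+1)$ values are fit with
a two-component mixture: a **dropout component anchored at zero** (mean
fixed at 0, scale free in [0.2, 1.0]) and a free normal expression
component, by EM. The posterior probability of the dropout component is
$d_{gc}$. Anchoring the low mode is essential: a mixture with two free
means will happily split any unimodal distribution in half and flag ~50%
of healthy observations as dropouts; anchoring encodes the actual
data-generating fact that dropouts sit at (or log-near) zero. Genes that
are all-zero in a group get $d = 1$ and are flagged unimputable; genes
whose expression mode collapses onto zero (essentially unexpressed) yield
no dropout calls.

Imputation is applied per cell to entries with $d_{gc} >$ `drop_thre`
(0.5), and — mirroring the two published gates — optionally only to genes
whose overall zero rate exceeds 50% (`apply_gene_gate`). The replacement
value is a non-negative least-squares prediction from the cell's top-$k$
Pearson-correlated neighbours in the same group ($k = \min(20,
\text{group size} - 1)$), fitted on the cell's reliable genes
($d \le$ `drop_thre`) and applied to the flagged ones. Reliable entries
are returned bit-identical; cells with fewer than 3 usable neighbours or 5
reliable genes are left unimputed and logged.

## Size factors

Four estimators, all rescaled to geometric mean 1:

* **RLE** — median ratio to the geometric-mean reference over genes
  positive in every cell. Undefined (raises) on sparse droplet counts
  where no such gene exists; this matches the estimator's definition
  rather than papering over it.
* **Upper-quartile** — 75th percentile of each cell's nonzero counts.
* **TMM** — trimmed (30% M, 5% A) weighted mean of M-values against the
  median-library reference column, combined with library size.
* **Deconvolution** (default) — cells are ordered by library size on a
  ring with alternating low/high interleaving, pooled at sizes
  21, 31, …, 101 from every start position; each pool's summed profile is
  compared with the average pseudo-cell by a median ratio, giving one
  linear equation per pool in the per-cell factors; the sparse system is
  solved by least squares with low-weight (0.1) library-size anchor rows
  for identifiability. Non-positive solutions are clipped to the smallest
  positive estimate with a warning.

The pipeline does not auto-select a method;
`preprocess.size_factor_stability` reports a gene-subsampling coefficient
of variation as a comparison diagnostic.

## Pathway activity and permutation test

Scores follow the weighted relative-expression definition in the README.
Entries with fewer than 3 usable genes are NaN (undefined), never 0 — a
zero would read as "strong depletion". The outlier rule (exclude a gene
from a pathway when its max relative expression over types exceeds
$Q_3 + 3\,\mathrm{IQR}$ of the pathway's pooled values) is deliberately
conservative, deterministic, and can be disabled (`outlier_rule=None`).

The permutation test shuffles cell-type labels across cells — within one
condition, since tumor and normal samples are scored separately — and
recomputes the *entire* pipeline including outlier exclusion each time, so
the null reflects every data-dependent step. Deviation is two-sided,
$|S - 1|$, because both elevated and depressed activities are of interest.
The $+1$ correction keeps $p \ge 1/(B+1)$. BH adjustment runs across all
defined (pathway × type) entries of a condition, matching a heatmap-wide
masking rule at $q \le 0.05$. Default $B = 1000$; the implementation
vectorizes permutations in batches through a single matrix product, so
$B = 1000$ on 2,000 cells × 50 pathways takes seconds.

## Per-cell GSVA scores

Per gene, a smoothed cumulative-density statistic across cells: Gaussian
kernel with the conventional bandwidth $s_g/4$ (use on log expression), a
Poisson kernel option for raw counts, and a plain `ecdf` option. Per
cell, genes are ordered by decreasing statistic (ties broken by gene
index) and given the symmetric rank weight $|p - k - p/2|$ at sorted
position $k$; the per-set random walk increments by normalized
$\text{weight}^\tau$ ($\tau = 1$) on set genes and decrements uniformly
otherwise. The default score is the magnitude-difference statistic
$\max(0, \max v) + \min(0, \min v)$; the classical signed maximum
deviation is available via `max_diff=False`.

One nuance: scores built on the *ecdf* statistic are exactly invariant to
any strictly monotone per-gene transformation (within-gene ranks are all
that enter). The Gaussian-kernel variant is exactly invariant to per-gene
affine maps but only approximately to nonlinear monotone maps, because
the bandwidth is data-dependent. Tests pin down both facts.

## Metabolic clustering

Per-cell scores are z-scored per pathway before the Euclidean distance is
computed, so a single high-variance pathway cannot dominate the metric —
a choice the clustering literature supports but which is recorded here as
this package's decision. Complete-linkage agglomeration, tree cut at
$k = 2$; the "high"/"low" names come from comparing the clusters' mean
per-cell mean scores (exact ties break to the first cluster with a
warning, never silently).

Re-clustering of a subset runs log-normalization → highly variable genes →
PCA (10 components) → shared-nearest-neighbour graph → Leiden modularity
communities at resolution 0.1, seeded for determinism; labels
`lmCluster0..m` are ordered by decreasing size. Subtype-composition
differences are tested per stratum pair with Pearson chi-square on the
2×2 table (no continuity correction), falling back to Fisher's exact test
when an expected count drops below 5, BH-adjusted across pairs.

## Markers and signatures

One-vs-rest contrasts: genes must be detected in ≥ `min_pct` (0.25) of
either group and show $|\log_2\mathrm{FC}| \ge$ 0.25, where log2FC =
$\log_2(\text{mean}(\mathrm{expm1}(x)) + 1)$ ratios on log-normalized
values (pseudo-count 1 keeps sparse genes bounded). The test is a
Wilcoxon rank-sum with tie-corrected normal approximation, BH within
contrast. Signatures take the top-$N$ genes by log2FC among those with
$q < 0.05$ (rank by p-value available via `rank_by="p"`); ties at rank
$N$ break lexicographically by gene id and the full selection rule is
recorded in the signature's provenance.

The gene-set counterpart (`vi_wilcoxon_gene_set_test`) ranks per-gene
log2FCs and tests each set's members against non-members, inflating the
normal-theory variance by $1 + (m-1)\bar{\rho}$ with $\bar{\rho}$ the mean
pairwise correlation of member genes — competitive set tests are
anti-conservative under inter-gene correlation without it.

## Survival

The cutpoint search enumerates every observed score value leaving at
least `minprop` (0.1) of samples on each side and maximizes the absolute
standardized log-rank statistic; ties take the lower cutpoint. The sweep
is incremental (each cell changes group exactly once across the sorted
candidate grid), so a full search is $O(n \cdot \#\text{event times})$
and the permutation-based selection-adjusted p-value (500 permutations by
default where requested) is cheap. Both the naive and the adjusted p are
reported, because the maximum of many correlated log-rank statistics is
not $\chi^2_1$. Kaplan–Meier estimation and the Cox fit (Efron tie
handling, Wald CIs) delegate to lifelines; constant covariates are
dropped with a warning, collinear designs raise, and fewer than 10 events
per covariate triggers a warning. Time units pass through unchanged.

## Pipeline

`pipeline.run` executes simulate → QC → normalize → (impute) → pathway
scoring → per-cell GSVA → metabolic clustering → markers → signature →
survival from one YAML-serializable config whose defaults carry the
analysis's operating point (500/1000/20% QC, drop_thre 0.5, deconvolution,
$k=2$, 10 PCs, resolution 0.1, min_pct 0.25, logfc 0.25, minprop 0.1).
Every random stage derives its seed from the config seed; outputs are
TSVs with fixed float formatting, and the manifest records SHA-256 hashes
per stage, so a re-run from the same config is byte-identical. Imputation
is off by default in the pipeline (it is quadratic-ish in cells and the
scoring stages are validated with and without it); the stage is enabled
with `impute: true`.

## Problem sizes used in verification

The shipped tests and `scripts/acceptance.py` use: 100 random small
instances for each scoring oracle (≤10 genes × ≤4 types; ≤20 genes × ≤5
cells); 2,000 cells × 50 pathways × 4 types with 500–1000 permutations
for calibration and planted-effect detection; 1,000 malignant cells for
high/low recovery; 500 cells × 2,000 genes for size-factor and marker
recovery; cohorts of 400–1,000 samples for survival. These sizes were
chosen so each check is statistically informative while a full
verification run stays around a minute on one CPU.

## Known limitations

* The imputation scheme is a simplification of the published
  scImpute-style procedure (zero-anchored normal mixture instead of a
  Gamma–Normal mixture); it preserves the thresholded decision rule and
  neighbour-regression fill but will differ numerically from the original.
* RLE size factors require a gene detected in every cell.
* GSEA p-values use plain gene-label permutations; no multilevel/exact
  refinement for very small p.
* The permutation null for pathway activity assumes exchangeable cells
  within a condition; strong within-sample correlation would make it
  optimistic.
* Survival simulation uses exponential baseline hazards and independent
  censoring; no competing risks or time-varying effects.
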
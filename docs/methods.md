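# Methods

`gutniche` re-implements, as a tested library, a cross-tissue single-cell
analysis of gastrointestinal stromal niches: starting from droplet
scRNA-seq digital gene-expression (DGE) matrices of stomach and
intestinal stromal cells, it identifies cell populations whose
transcriptome signatures are conserved between the two tissues, and
carries the companion analyses — diffusion imputation and marker
co-expression, gene-set and disease-gene enrichment, random-forest cell
similarity, and cross-tissue enhancer comparison. Every stage is
exercised end-to-end on synthetic data with known ground truth; this
note records the models, the defaults and why, and what the synthetic
results do and do not establish.

## Clustering path

Genes detected in fewer than 3 cells are removed, then cells detecting
fewer than 100 (stomach) or 150 (intestine) of the retained genes; the
filter runs genes-then-cells in a single pass, with no fixed-point
iteration. Counts are CPM-normalized per cell and transformed as
ln(1 + CPM) (pseudocount 1, natural log — the dominant convention).
About 2000 highly variable genes are selected by binning genes into 20
equal-count bins of mean log expression and z-scoring the dispersion
(variance/mean) within each bin; ties break by gene id so the selection
is deterministic.

PCA runs on the per-gene z-scored HVG submatrix. The number of
components kept follows a plateau rule on the component standard
deviations: keep the smallest *i* such that **every** later drop
`(sd_j − sd_{j+1})/sd_1, j ≥ i` is below `elbow_tol` (default 0.005).
The "every later drop" form matters: with several comparable signal
components, consecutive drops inside the signal regime are already
tiny, and a first-drop rule would truncate inside the signal; the
plateau-onset form keeps all components up to the noise floor, returns
1 component on isotropic noise, and returns `pca_max` when the curve
never flattens.

Two-dimensional t-SNE (scikit-learn, PCA initialization, fixed seed,
perplexity 30) embeds the PC scores, and clusters are called by DBSCAN
on the embedding — the classic single-cell density-clustering recipe
operates on the 2-D map. `cluster_eps` defaults to 2.5, a scale that separates blobs at
perplexity-30 embedding geometry; `cluster_min_pts` defaults to 10.
DBSCAN noise points join their nearest clustered neighbour, and cluster
ids are relabeled by decreasing size. Cluster counts on real stromal
datasets (tens of clusters) depend sensitively on these density
parameters and are not treated as reproducible targets.

## Differential expression

Markers come from the bimodal ("bimod") likelihood-ratio test: a gene's
log expression in a cell group is a point mass at zero with probability
1 − π plus Normal(μ, σ²) for expressing cells (`expressing` = log value
> 0, consistent with the pseudocount-1 transform). MLEs are π̂ =
n_expr/n and μ̂ = mean over expressing cells; σ̂ is pooled over both
groups with a floor of 0.01. LR = 2(llA + llB − ll_pooled) refers to
χ² with 2 df (π and μ free per group). A gene expressed in no cell gets
LR = 0, p = 1. Multiple testing uses Bonferroni within cluster. Ranking
for top-k selection is p ascending, |log fold-change| descending, then
gene id; only positive-fold genes qualify. The ranking key is a
documented design choice — the test itself does not prescribe an
ordering. k = 30 builds conservation features; k = 20 builds the forest
similarity features.

## Cross-tissue conservation

Each cluster's profile is its mean log-CPM over a shared feature space:
the union of every cluster's top-30 markers from both tissues,
restricted to genes present in both matrices, sorted. Union rather than
intersection preserves every cluster's discriminative genes. Profiles
stay on the log-CPM scale (not z-scored) — Spearman is rank-based, so
monotone per-profile transforms are irrelevant, and log-CPM avoids
cross-tissue scaling artifacts. Stomach × intestine cluster pairs are
compared by Spearman ρ with average-rank ties; pairs with ρ ≥ 0.7 are
called conserved. Constant profiles have undefined ρ and never match.
All clusters of both tissues also enter an average-linkage dendrogram
with distance 1 − ρ (marker-feature profiles by default).

Matches are validated by supervised neighbor voting (MetaNeighbor
style): cells of both tissues combine into one cell × cell Spearman
network over HVGs (computed by this package's binned-dispersion
selector, the same binned-variance scheme MetaNeighbor's
get_variable_genes uses), each row
rank-standardized to [0, 1]. For each type, one tissue's labels are
hidden; hidden cells receive votes from the visible cells of the type,
normalized by total connectivity to visible cells, and the AUROC of the
votes over the truly positive hidden cells is averaged over the two
hide directions. A type present in one tissue only has no computable
direction and is flagged rather than scored.

## Diffusion imputation and co-expression

The dropout-correcting operator is the MAGIC adaptive kernel with
knn = 10 and decay exponent α = 15 (MAGIC's k and a, in its own
parameter names):
σᵢ = distance (in PC space) to the 10th neighbour,
K = exp(−(d/σᵢ)^α), symmetrized as (K + Kᵀ)/2, row-normalized to a
Markov matrix M. Expression diffuses t steps (default t = 3, the MAGIC reference
implementation's default). No
post-diffusion rescaling by default. Duplicate cells (σ = 0) have their
bandwidth floored at the smallest positive distance with a warning.
A gene is called expressed in a cell when its (imputed) value strictly
exceeds the gene's mean over all cells; two genes co-express in the
cells passing both cutoffs.

## Enrichment

*GSEA.* Genes are ranked by signal-to-noise over cluster-average
profiles contrasting conserved vs distinct cluster groups, with each
group's sd floored at max(0.2·|μ|, 1e-6). The enrichment score is the
classic weighted running sum (weight p = 1): hits advance by
|score|^p/Σ_hits|score|^p, misses retreat by 1/(N − n_set); ES is the
extremum. Significance uses **gene-set permutation** — the "samples"
here are a handful of cluster averages, far too few for phenotype
permutation — with size-matched random sets: NES = ES / mean |null ES|
of the same sign, p = (1 + #{|null ES| ≥ |ES|})/(n_perm + 1), and FDR
by the NES-ratio procedure. The two-sided extremeness in p is what
makes the null calibration exact: a random set's |ES| is exchangeable
with its own null draws, so p is discrete-uniform.

*ORA.* Upper-tail hypergeometric P(X ≥ overlap) per set with
Benjamini–Hochberg across sets; exact against enumeration for small
universes.

*Disease genes.* Every gene's log-CPM is z-scored across all cells;
cluster means of the z-scores form a gene × cluster matrix; genes with
any cluster mean z > 1.65 (one-sided 5% of a standard normal) are
retained, restricted to the trait's genes for reporting. Retained genes
cluster by Euclidean distance with complete linkage — the defaults of
R's hclust/dist, the routine this step standardizes on. Zero-variance genes are
excluded with a log entry.

## Forest similarity (RAFSIL-style)

Cells are pooled in seeded random groups of 20 within each (type,
tissue); a remainder of at least pool_size/2 keeps its own pool, a
smaller one merges into the last full pool (pooling in groups of 20
leaves remainders underdetermined; this rule is explicit and seeded). Pool
profiles are mean log-CPM. Features are the union of each cluster's
top-20 markers, replacing RAFSIL's internal feature construction with
the biologically chosen marker space. Per repeat, a synthetic background permutes
each feature column independently; a random forest (500 trees per
repeat, 10 repeats) separates real from synthetic pools; proximity is
the fraction of trees in which two real pools share a terminal leaf,
and dissimilarity = 1 − mean proximity over repeats. This is the
RAFSIL1-style unsupervised variant, RAFSIL's primary algorithm. Forest
sizes are exposed parameters.

## Region comparison

Region sets merge by sweep-line union (overlap ≥ 1 bp by default),
recording provenance; chromosome naming conventions must agree —
no chr-prefix guessing. Sample correlation is Pearson on
log2(signal + 1). For the MA classification, each sample is scaled to
equal total signal, per-tissue means are formed, and the
orientation-free fold (higher + 1)/(lower + 1) is compared with the
two thresholds: fold < 1.5 → common, fold > 2 → specific to the higher
tissue, otherwise ambiguous. A = mean of log2 signals, M = signed log2
ratio. The normalization (equal-total scaling + pseudocount 1) is the
minimal robust choice for comparing signal between tissues. Overlap counts are A-sided
(number of A regions hit ≥ 1 B region), verified against a quadratic
oracle. Nearest-gene assignment takes the TSS closest to the region
midpoint, distance 0 if the TSS lies inside, ties alphabetical.

## Synthetic data: what it emulates

`simulate_two_tissue` generates the two tissues' sparse NB count
matrices. Baseline relative gene abundances are log-normal
(`baseline_sigma` = 0.5). Each cell type is a **global expression
program**: a mean-one log-normal modulation of every gene
(`type_effect_sigma` = 0.5), because distinct cell lineages differ
transcriptome-wide — a generator in which types differ only at their
markers makes every pair of types identical on most feature genes, and
no threshold near 0.7 can then separate conserved from non-conserved
pairs (the cross-type profile ρ floor sits at ~0.71 even for a flat
baseline). A shared type reuses the identical program vector in both
tissues; that sharing *is* the planted conserved signature. On top of
its program, each type's disjoint 30-gene marker block is multiplied by
`marker_fold` (default 8) and exempted from its own modulation, so the
planted markers carry exactly the configured fold. Library sizes are
log-normal (mean 2000 UMIs, sigma 0.35 — heavy-tailed droplet depth);
counts are Gamma-Poisson with var = μ + 0.3 μ²; optional Bernoulli
dropout with logistic keep-probability in log mean is off by default.

Two dedicated genes outside the marker blocks form the planted
co-expression pair: ~0.05 expected UMI/cell everywhere except shared
program 0, where both genes sit at ~4 UMI/cell. This on/off structure
mirrors real population-restricted marker pairs; a pair with
substantial baseline expression everywhere has no well-defined
"co-expressing population", and library-depth assortativity of the kNN
graph leaves depth-correlated joint noise that a mean cutoff cannot
separate.

Defaults — 8 shared types, 3 stomach- and 2 intestine-specific types,
300 cells per type, 30 markers at 8-fold, 2000 genes — are the
package's reference study conditions, sized so every stage runs on one
CPU in minutes. Under them (seed 1): Spearman matching at 0.7 recovers
the conserved pairs with precision = recall = 1 (conserved ρ ≈ 0.985,
best non-conserved ρ ≈ 0.43); t-SNE/DBSCAN clustering reaches ARI 1.0;
the separation margin (conserved ρ minus best off-pair ρ) increases
strictly over marker folds 2 → 4 → 8. The conserved-pair ρ itself
saturates near 0.985 at every fold — conserved types share their whole
program, so pair recovery does not depend on the marker fold; the
margin is the quantity the fold moves.

What passing these tests does **not** show: the generator has no batch
effects, doublets, ambient RNA, or cell-cycle structure; types are
equally sized and well separated; the region simulator plants clean
fold differences with log-normal replicate noise only. Real-data
performance — and genome-scale quantities such as cluster counts or
common super-enhancer tallies from full ChIP-seq workflows — depends
on raw data and upstream processing outside this package's scope.

`simulate_region_signals` plants common regions (equal expected signal
in both tissues) and tissue-specific regions (≥ 4-fold expected
difference; the floor keeps the planted truth outside the ambiguous
band) with two replicates per tissue and log-normal noise of a given
CV. `simulate_disease_table` draws one trait's genes from a chosen
type's markers plus uniform background genes.

## Numerical choices and degenerate inputs

Seeds: one global seed fans out to per-stage seeds by CRC32 of the
stage name, so changing one stage's internals never perturbs another
stage's draws; all derived seeds stay below 2³¹. Duplicate gene ids on
input are summed (deterministic DGE-collapse behaviour), never dropped.
Genomic coordinates are 0-based half-open everywhere internally.
Zero-variance genes: z-scoring substitutes sd 1 (scaled layer),
disease-z excludes the gene, the forest refuses all-constant feature
sets. All-zero signal regions classify as common and are flagged.
Spearman on constant profiles is recorded missing, never matched.
An empty QC result raises with the surviving-dimension report rather
than propagating empty matrices.

## Known limitations

t-SNE and DBSCAN hyperparameters interact; on data with touching
populations the 2.5/10 defaults will merge or shatter clusters, and the
embedding-based clustering inherits t-SNE's seed sensitivity even
though every run here is seeded. The bimod LRT treats cells as
independent and ignores depth beyond CPM. Gene-set permutation answers
a different null than phenotype permutation (set coherence vs class
association). The forest proximity depends on feature scaling only
through tree splits, but its Monte-Carlo noise requires hundreds of
trees for stable entries. Pipeline-scale runs hold dense matrices in
memory; the implementation targets desk-scale studies (thousands of
cells), not atlases.
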
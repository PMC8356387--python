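# Methods

This note describes the models and estimators in `snconcord`, the defaults
and why they were chosen, and what the synthetic data does and does not
capture.

## The synthetic droplet model

The generator emulates a paired experiment in which one islet preparation is
split and profiled both as dissociated whole cells (scRNA-seq) and as
isolated nuclei (snRNA-seq), optionally alongside a xenograft sample of human
islet nuclei recovered from a mouse host.

**Expression programs.** All cell types share one baseline abundance vector.
Protein-coding and mitochondrial baselines are symmetric-Dirichlet(0.5)
masses (chi-square(1) draws, normalised), which gives the heavy right skew of
real transcriptomes. lncRNA baselines are drawn iid lognormal (σ = 0.5)
around 0.12× the mean protein-coding mass: lncRNAs are modelled as a
uniformly low-expressed band with moderate dispersion rather than
chi-square-tailed, because real lncRNA expression sits well below coding
genes and because chi-square tails would make nuclear-enrichment detection
power bimodal (the top tail saturates detection at deep libraries, the bottom
tail is too rare to test) in a way that reflects the baseline draw rather
than the retention biology under study.

Each type multiplies a disjoint set of `markers_per_type = 20` coding genes
by `marker_fold = 8` and renormalises. Marker genes are assigned the mean
non-marker baseline before boosting, so the realised marker/non-marker mass
ratio equals the configured fold; the first (hallmark) marker of each type —
the hormone gene where a canonical name applies (INS, GCG, SST, PPY) — gets
an extra 3× (`hallmark_extra`), reflecting the dominance of hormone
transcripts in endocrine cells and guaranteeing that INS is the
highest-mass gene of the β program.

**Modality effects.** Nuclear modalities multiply lncRNA mass by
`lncRNA_retention_factor` (default 3) and renormalise. Every modality then
rescales the 13-gene mitochondrial block to an exact target share of the
transcriptome: 4.2% (whole cells), 2.7% (nuclei), 1.5% (graft nuclei) —
whole-cell droplets carry more mitochondrial RNA because the cytoplasm comes
along. Library sizes are lognormal: median 6000 UMI for cells, 4500 for
nuclei, 4000 for graft nuclei (log-sd 0.35), reflecting the lower RNA content
of nuclei.

**Droplet composition.** A droplet is a singlet (type drawn from the
configured proportions), a doublet (probability `doublet_rate = 0.08`;
average of two independently drawn type programs, library × 1.6), or empty
(`n_empty_droplets = 300` per modality; lognormal library with median 50).
Every non-empty droplet mixes its program with the ambient profile —
the abundance-weighted mixture of all type programs — at a per-droplet
fraction ρ ~ Beta with mean `ambient_level` and concentration 50. Ambient
means default to the modality-specific levels a contamination-removal tool
reports on such data: 5.87% (cells), 1.42% (nuclei), 4.6% (graft nuclei).
Counts are one multinomial draw of the library size over the gene space, so
column sums equal the drawn library sizes exactly.

**Xenograft admixture.** Graft droplets append a 500-gene mouse block with
its own Dirichlet(0.5) profile. The per-droplet mouse fraction comes from a
two-component Beta mixture: Beta(3, 57) for mostly-human droplets
(mean 5%) and Beta(10, 7) for mouse-dominated droplets (mode 0.6), with 10%
weight on the contaminated component. Empty graft droplets take the clean
component. Counts are drawn jointly over human+mouse genes in one
multinomial.

**Cell-type proportions.** α 0.35, β 0.30, δ 0.10, PP 0.05, ductal 0.10,
other 0.10 — plausible islet composition with PP deliberately rare, so the
pipeline is tested on recovering a low-abundance population. These are
arbitrary defaults, not measured values.

**Seeds.** All randomness flows from `numpy.random.default_rng`. Paired
experiments derive per-modality seeds as `seed + {1, 2, 3}` for whole-cell /
nucleus / graft, so each modality has an independent but reproducible stream;
regenerating with the same config and seed is bit-identical.

**What the generator does not model:** batch/donor effects, sequencing
saturation, gene length or GC bias, barcode swapping, transcriptional
bursting beyond multinomial noise, intronic vs exonic reads, and real
correlation structure between genes beyond the shared-program mixture.
Passing tests therefore demonstrate that the estimators recover the
parameters of *this* model at realistic sizes — not that they match any
particular tool's behaviour on real sequencing data.

## QC estimators

**Empty-droplet calling.** A two-component Gaussian mixture on
ln(total UMI + 1); droplets with posterior > 0.5 in the low-mean component
are empty, and the ambient profile is their pooled, normalised counts. This
is a deliberately light stand-in for a deep generative ambient model: it
keeps the published decision rule (posterior above one half) while replacing
the expression-level model with a library-size mixture. A fit whose modes sit
closer than 2 natural-log units is declared degenerate: nothing is flagged
and the ambient profile falls back to the lowest 1% of droplets by UMI.

**Ambient-fraction estimation.** Non-empty droplets are coarse-grouped
(k-means, default 5 groups, on 20 PCs of ln-CP10K counts). For droplet *d*
with counts *x* and group centroid *c*, the estimate maximises the
multinomial log-likelihood Σ_g x_g ln((1−ρ)c_g + ρa_g) over ρ ∈ [0, 1]
(bounded 1-D search, tolerance 1e-4). Because the empirical centroid itself
contains ambient reads, the raw estimator is biased low by roughly the
group-mean ambient fraction; the centroid is therefore purified —
π̂ = (c − ρ̄a)/(1 − ρ̄), clipped and renormalised — and the estimates
recomputed until the group means move by less than 5e-4 (at most 30 rounds).
With deep libraries (≥ 5000 UMI) this recovers per-droplet fractions around
a 5% mean with mean absolute error ≈ 0.02.

**Doublet scoring.** Artificial doublets (25% of n) are sums of random
droplet pairs; real and artificial droplets share a 30-PC embedding of
ln-CP10K counts (PCA fitted on real droplets only), and each real droplet's
score is the fraction of artificial droplets among its 20 nearest
neighbours. The top `expected_doublet_rate` quantile is flagged, ties broken
by barcode order so the flag count is exact. Only heterotypic doublets are
detectable in principle; homotypic doublets are indistinguishable from large
singlets in this embedding, as in any artificial-neighbour scheme.

**Filter cascade.** Removal order: empty → doublet → droplet thresholds →
mouse-gene strip (graft) → gene filter. Thresholds use strict inequalities
for removal ("more than 20% mito", "more than 25% mouse", "UMI < 1000",
"genes < 500"), so boundary droplets survive; the gene filter ("detected,
i.e. ≥ 1 UMI, in at least 3 cells") runs last so it refers to surviving
droplets. Graft UMI/gene floors are applied *before* mouse genes are
stripped — a choice, since metrics are computed on the full droplet content.
Per-stage tallies always sum to input − output.

## Clustering and annotation

ln(1 + count) is the working transform throughout. Two variants are emitted:
raw ln counts for all concordance statistics (the comparisons are defined on
"natural log of counts"), and depth-scaled ln(1 + CP10K) for clustering only,
where library-size differences would otherwise dominate the embedding.

Clustering: top-2000 variable genes → per-gene standardisation → 25
principal components (full SVD, deterministic) → kNN graph (k = 15,
symmetrised) → Leiden modularity communities at resolution 1.0 with a fixed
seed. Cluster ids are relabelled by decreasing size, ties broken by the
smallest contained droplet index.

Annotation is at cluster level: the cluster centroid (mean ln counts) is
Pearson-correlated with each reference type's expected ln profile,
ln(1 + S·π_t) with S the median droplet library size, over the shared gene
space; argmax wins. Clusters below correlation 0.5 keep their argmax label
but are flagged low-confidence. This centroid-correlation transfer is a
simple, auditable stand-in for anchor-based reference projection; it assumes
cluster purity, which holds when clustering resolution is adequate.

Markers: per gene and cluster, one-sided Wilcoxon rank-sum (in-cluster vs
rest) on ln values, BH-corrected within cluster; a marker needs q ≤ 0.05 and
a positive mean difference.

## Concordance statistics

* Detected gene set: ≥ 1 UMI in ≥ 3 droplets. Overlap is reported both as
  Jaccard and as intersection over the smaller set — the two readings of a
  single "percent overlap" figure — and neither is privileged.
* Per-type correlation: Pearson r of mean ln counts per gene over the
  intersection of detected sets, R² = r², two-sided p for r ≠ 0
  (equivalent to the F-test of the least-squares line of one dataset's means
  on the other's). Types are compared all-vs-all, so matched and mismatched
  pairs are always available side by side.
* Top-N overlap: genes ranked per type by mean ln counts, descending, ties
  broken lexicographically by gene id for determinism; overlap is
  |topN(A) ∩ topN(B)|/N for N ∈ {100, 200, 500, 1000}. Ranking by marker
  score instead of mean expression was considered and rejected as the
  default: mean-expression ranking is the direct reading of "top genes" and
  needs no second model.
* Detection enrichment: per-gene detection percentages in the two datasets;
  fold change pct_sn/pct_sc (infinite folds flagged, not silently dropped);
  significance by a pooled two-proportion z-test on the detection counts
  (vectorised; Fisher's exact available for small counts), BH across genes;
  enriched = fold > 1.5 and q ≤ 0.05. Detection is computed over all
  QC-passing droplets; per-type rates are a documented variant, since it is
  ambiguous which a given published table uses.

## Numerical and degenerate-input choices

* Zero-total droplets get mito/mouse fractions 0 (0/0 convention).
* A likelihood mixture component of exactly 0 under a positive count gets an
  epsilon (1e-12) rather than −inf.
* Quantile flag counts use round(rate × n) with stable argsort, so flag
  counts and tie behaviour are exact and order-independent claims are
  testable.
* Standard deviations of constant genes are set to 1 before standardising
  (the gene then contributes nothing).
* All tables are written with fixed float formatting and sorted JSON keys so
  a fixed seed reproduces outputs byte for byte.

## Problem sizes

Defaults (1200 real + 300 empty droplets per modality, 2000 human genes, 500
mouse genes) were chosen so a full paired run — simulation, QC, clustering,
annotation, concordance — completes in well under a minute on one CPU while
keeping every per-type statistic (including the 5% PP population) estimable.
They are package defaults, not claims about real experiment scale; real
datasets are one or two orders of magnitude larger in both genes and
droplets.

## Known limitations

* The empty-droplet and ambient estimators assume a bimodal library-size
  distribution and a single shared ambient profile; gradual barcode-rank
  "knees" and sample-specific ambient pools are out of scope.
* Cluster-level annotation cannot split a mixed cluster; resolution must be
  high enough that clusters are type-pure.
* The two-proportion z-test is asymptotic; for very low detection counts use
  `method="fisher"`.
* Doublet recall is defined against heterotypic doublets only.
* The generator's concordance is high by construction (shared programs);
  the statistics quantify *recovered* structure, they cannot calibrate what
  R² a real cross-protocol comparison should reach.
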
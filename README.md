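# snconcord

Tools for asking a practical question in islet transcriptomics: **is
single-nucleus RNA-seq (snRNA-seq) a faithful substitute for single-cell
RNA-seq (scRNA-seq)?** Nuclei can be prepared from frozen or engrafted tissue
that is not amenable to live-cell dissociation, so the answer matters to
anyone studying archived human pancreatic islets or islets transplanted into
mice.

The package implements the full desk side of such a comparison:

* **`snconcord.simgen`** — a synthetic droplet-count generator. All cell types
  share one baseline expression program; each type boosts a disjoint marker
  set (INS for β-cells, GCG for α-cells, SST for δ, PPY for PP, CFTR/SOX9/
  KRT19 for ductal). Modalities differ in library size, mitochondrial UMI
  share, ambient contamination level and nuclear lncRNA retention; droplets
  can be singlets, doublets or empty, and xenograft nuclei carry a
  per-droplet mouse-UMI fraction from a two-component Beta mixture. Ground
  truth for every droplet is returned, so each downstream stage is testable.
* **`snconcord.dropqc`** — droplet QC: per-droplet UMI/gene/mito/mouse
  metrics, empty-droplet calling (posterior > 0.5 in a two-component mixture
  on log library size), ambient-fraction estimation by per-droplet maximum
  likelihood, artificial-doublet kNN scoring, and the filter cascade
  (genes detected in ≥ 3 cells, ≥ 200 genes per droplet, > 20% mito removed,
  > 25% mouse UMI removed and all mouse genes stripped in graft mode, graft
  droplets additionally need ≥ 1000 UMI and ≥ 500 genes).
* **`snconcord.celltyping`** — ln(1+count) normalisation, PCA (25 components)
  + kNN graph + Leiden clustering, reference-centroid cell-type annotation,
  Wilcoxon rank-sum marker detection with BH correction.
* **`snconcord.concord`** — the concordance statistics: detected-gene-set
  overlap (Jaccard and percent-of-smaller), per-cell-type R² (the squared
  Pearson correlation of mean ln counts per gene between datasets), top-N
  gene overlap (N = 100, 200, 500, 1000), and detection-rate enrichment
  (fold > 1.5 at FDR 0.05) with biotype breakdown.
* **`snconcord.io` / `snconcord.cli`** — 10x-style Matrix Market bundle
  readers/writers (species-prefixed feature ids for xenografts), YAML
  configs, and a CLI (`snconcord simulate|qc|annotate|concord|run`).

## Worked example

```python
import snconcord as s

cfg = s.SimulationConfig(seed=3)                      # paired design, 1200 droplets/modality
exp = s.simulate_paired_experiment(cfg, seed=3)

params = s.AnalysisParams(seed=3)
filtered, labels = {}, {}
for modality, matrix in exp.matrices.items():
    fmat, report = s.run_qc(matrix, s.QCThresholds(), seed=3)
    clusters = s.reduce_and_cluster(s.normalize_ln(fmat, depth_scale=True), params)
    labels[modality] = s.annotate_clusters(
        s.normalize_ln(fmat), clusters, fmat.gene_ids, exp.profiles, params)
    filtered[modality] = fmat
    print(modality, report.tallies)

report = s.compare_datasets(
    filtered["nucleus"], filtered["whole_cell"],
    s.normalize_ln(filtered["nucleus"]), s.normalize_ln(filtered["whole_cell"]),
    labels["nucleus"]["cell_type"], labels["whole_cell"]["cell_type"],
    exp.profiles.genes)
print(report.gene_set_stats)
matched = report.correlations.query("type_a == type_b")
print(matched[["type_a", "r2"]])
```

prints (seed 3):

```
whole_cell {'n_droplets_in': 1500, 'removed_empty': 300, 'removed_doublet': 96,
            'removed_droplet_thresholds': 0, 'n_droplets_out': 1104, ...}
nucleus    {'n_droplets_in': 1500, 'removed_empty': 300, 'removed_doublet': 96,
            'removed_droplet_thresholds': 0, 'n_droplets_out': 1104, ...}
{'n_a': 1964, 'n_b': 1966, 'n_intersection': 1959,
 'jaccard': 0.9939117..., 'percent_of_smaller': 99.74541...}
type_a     r2
ductal 0.9606
  beta 0.9647
 alpha 0.9635
 other 0.9608
 delta 0.9598
    PP 0.9545
```

Reading: QC drops the 300 simulated empty droplets and the expected 8% of
doublets in each modality; the two modalities detect near-identical gene sets
(99.7% of the smaller set) and every matched cell type correlates at
R² ≈ 0.96, while mismatched type pairs stay visibly lower — the signature of
cell-type-specific concordance between the two protocols.

The same run from a shell:

```bash
snconcord run --out run_out --seed 3
```

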
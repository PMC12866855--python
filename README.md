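# oncotme

Downstream analysis of two-condition (oncogene **ON** vs **OFF**) tumor
single-cell RNA-seq, for studies that switch a driver oncogene off (e.g.
doxycycline-controlled Kras^G12D^ in a liver-cancer model) and ask how the
tumor microenvironment responds. The package implements the full
post-clustering computation as a tested library with numbered analysis
drivers, plus the tumor-burden metrics used alongside such experiments:

- **QC and normalization** — cells with fewer than 200 detected genes or more
  than 10% mitochondrial content are excluded; counts are scaled to CPM
  (counts per million per cell).
- **Marker-panel annotation** — clusters (labels are taken as input;
  clustering itself is out of scope) are assigned cell types by mean
  log1p(CPM) over curated mouse marker panels (Ptprc; Csf1r/C1qa/Cd68/Ccr2;
  S100a8/Cxcr2; Cd3d/Cd3e; Pecam1/Flt1; Xcr1/Cd209a; Krt8/Krt18/rtTA3;
  Dcn/Col1a1/Acta2; Cd79a/Cd19/Igkc), with an explicit "ambiguous" fallback.
- **Composition shifts** — cell-type and T-cell-subpopulation (Cd8a+, Cd69+,
  double-positive, Ncr1+) abundance is cross-tabulated ON vs OFF and tested
  type-vs-rest with two-sided Fisher exact tests, BH-adjusted.
- **Ligand–receptor scoring** — for every ordered (sender, receiver) cluster
  pair and condition, score = mean CPM(ligand | sender) × mean
  CPM(receptor | receiver), with a strict >0.1 CPM detection gate on both
  means, strict >20 prioritization in at least one condition, and a ×10
  scaled copy for visualization only. OFF − ON deltas rank
  condition-dependent interactions.
- **Pathway enrichment** — per-cluster one-vs-rest Wilcoxon marker genes are
  tested against GMT gene sets with the exact upper-tail hypergeometric
  probability

  ```
  p = P(X ≥ k) = 1 − Σ_{i<k} C(K,i) C(N−K, n−i) / C(N,n)
  ```

  (N background universe, K pathway size, n markers, k overlap), after
  pooling clusters with n < 50 cells; BH within each (pooled) cluster.
- **Tumor burden** — ellipsoid caliper volume V = π·L·W²/6, per-subject
  baseline-relative burden series, percent change, mean ± SD group summaries.
- **Synthetic data** — a seeded negative-binomial simulator (variance
  μ + μ²α, Bernoulli dropout) generates two-condition datasets with planted
  ground truth: a T-cell expansion after oncogene withdrawal, a
  Cd8a/Cd69/Ncr1 positivity shift, an Il15 (tumor cluster) → Il2rb (T-cell
  cluster) interaction among 60 decoy pairs, a planted pathway among 59
  decoys, and realistic QC failure modes, so every stage is testable without
  sequencing data.

## Worked example

The numbered drivers under `analysis/` run the whole study on the shipped
synthetic dataset (2000 cells per condition, 15 clusters, seed 1) and write
tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_qc_annotate.py
python analysis/03_composition.py
python analysis/04_lr_scores.py
python analysis/05_pathway_enrichment.py
python analysis/06_tumor_metrics.py
```

Selected output (what the scripts actually print):

```
QC: retained 3653/4000 cells (111 low-gene, 243 high-mito)
...
      cell_type   a   b    c    d  odds_ratio      p_value      q_value
        T cells 347  95 1485 1726    4.245416 9.383206e-39 7.506565e-38
...
enriched in OFF at q<0.05: B cells, CAFs, T cells
...
strongest condition-dependent interaction: Il15 (cluster 13) -> Il2rb (cluster 4), delta = 23683
...
group               pathway    N  K  n  k      p_value      q_value  significant
    4 PLANTED_TCELL_PROGRAM 2000 50 33 22 4.447354e-30 2.668412e-28         True
...
luminescence change day 0 -> 7: -99.0%
```

Reading this: after simulated oncogene withdrawal the T-cell compartment
expands about four-fold (Fisher exact odds ratio 4.2, q ≈ 8e-38), the
planted Il15→Il2rb tumor→T-cell interaction is the strongest
condition-dependent ligand–receptor signal, the pathway planted on the
T-cell program is the only significant enrichment hit (22 of its 50 genes
overlap the 33 cluster-4 markers), and a cohort regressing at ln(100)/7 per
day loses 99% of its bioluminescent burden by day 7 — exactly the planted
ground truth, recovered end to end.

The same stages are exposed as a CLI (`oncotme simulate|qc|annotate|markers|
composition|score-lr|enrich|tumor|run-all`) and as one call,
`oncotme.pipeline.run_all(config, outdir)`, which writes every intermediate
table plus a run log and a SHA-256 manifest and is byte-deterministic under
(config, seed).

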
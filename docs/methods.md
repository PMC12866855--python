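# Methods

This note documents the models, defaults and design choices behind the
package; it states nothing the tests or `scripts/acceptance.py` do not
themselves compute.

## Scope and data model

The package covers the *downstream* computation of a two-condition tumor
scRNA-seq comparison. Upstream steps — alignment, normalization for
clustering, HVG selection, integration, graph clustering, UMAP — are out of
scope; cluster labels arrive as input in the cell metadata. Counts live in
an `AnnData` (cells × genes, raw integers); on disk the canonical format is
a genes-as-rows Matrix Market triplet with `genes.tsv` and `barcodes.tsv`
sidecars (barcode, condition, cluster), plus TSV for every report, GMT for
gene sets, and YAML for pipeline configuration. All writers emit
deterministic column order, header rows and LF endings.

## QC and normalization

A gene is *detected* in a cell if its raw count is > 0 (the conventional
reading). Cells are excluded when they have fewer than `min_genes = 200`
detected genes or more than `max_mito = 0.10` mitochondrial content
(mito counts / total counts over genes named `mt-*`). Because both rules
are exclusions stated as strict inequalities, the boundaries — exactly 200
genes, exactly 10% — are retained. The filter is idempotent and reports
removals per criterion.

CPM is count/total × 1e6 per cell, computed after QC (zero-total cells are
a hard error pointing at QC). *Mean CPM of a cluster* is the arithmetic
mean of per-cell CPM with zeros included — an average over cells — not the
CPM of pooled cluster counts; the two differ whenever library sizes vary
within a cluster, and the per-cell average is what the ligand–receptor
score consumes.

## Cluster annotation

Per cluster, each candidate type is scored as the mean of log1p(mean CPM)
over its panel genes; the top type is assigned only if its score is
positive and at least `margin = 1.2` times the runner-up, otherwise the
cluster is labeled "ambiguous" — no silent tie-breaking. The margin is a
free choice (no tie rule is standard); 1.2 is wide enough that a pan-immune
score (Ptprc alone) does not beat a specific immune panel, and narrow
enough that silent clusters stay ambiguous. Panel genes missing from the
matrix are dropped with a warning.

## Marker genes

The marker finder is a documented stand-in for Seurat-style
`FindMarkers` defaults, not a claim of equivalence to any specific tool:
one-vs-rest two-sided Wilcoxon rank-sum (Mann–Whitney U, normal
approximation with tie and continuity correction) per gene on CPM,
BH-adjusted across genes within each cluster; a marker must have q < 0.05
and be up-regulated with log2((mean_in+1)/(mean_out+1)) ≥ 0.25. Constant
genes get p = 1. Selection is invariant to globally rescaling CPM (rank
test + ratio fold-change) and is deterministic.

## Composition testing

Cell types (and T-cell subpopulations) are cross-tabulated by condition and
each row is tested type-vs-rest × OFF-vs-ON with a two-sided Fisher exact
test using the point-probability convention (sum of all fixed-margin tables
whose probability does not exceed the observed table's); sidedness is a
choice — two-sided is the common default. Multiple testing across rows uses
BH (configurable, including "none"); raw p is always reported. The odds
ratio is the sample OR with a Haldane–Anscombe 0.5 correction when any cell
is zero; zero-margin rows report p = 1 and a missing OR. Subpopulation
positivity uses raw count ≥ 1 by default — the simplest dropout-robust
rule, exposed as a flag — and subpopulation rows overlap (double-positives
are a subset of each single-positive), so their 2×2 tables are built
against the *parent* population totals.

## Ligand–receptor scoring

For each (ligand, receptor) pair, ordered cluster pair (sender, receiver) —
self-pairs included, autocrine signaling is real — and condition:

    score = mean CPM(ligand | sender) × mean CPM(receptor | receiver)

Detection requires *both* means strictly above 0.1 CPM (the gate is on the
cluster mean, not on a per-cell detection fraction — a documented
assumption); undetected records keep their means but report score 0 rather
than disappearing, so the output stays auditable. A (pair, sender,
receiver) triple is *prioritized* iff its unscaled score exceeds 20 in at
least one condition, strictly; the ×10 visualization scaling is applied
after thresholding and never feeds any decision. Condition contrast is the
arithmetic delta score(OFF) − score(ON) and a pseudocount ratio
(OFF + ε)/(ON + ε) with ε = 1. The score is deterministic; no permutation
null is attached (it is a score, not a test). A small curated mouse pair
table ships as the default (including Il15–Il2rb and Il15–Il15ra); user
tables override it.

## Pathway enrichment

`hypergeom_upper(N, K, n, k)` is the exact upper tail P(X ≥ k) of the
hypergeometric distribution, computed via scipy's log-space survival
function so N = 20000 is numerically stable; k = 0 returns exactly 1.
Marker and pathway genes are intersected with a declared universe first, so
(N, K, n, k) stay self-consistent; off-universe markers are dropped with a
warning. Clusters with fewer than 50 cells are pooled before testing
(default: all small clusters into one group, marker sets unioned, sizes
summed; a user pooling map overrides). BH is applied within each (pooled)
cluster across pathways.

The background N is configurable: ~20000 (protein-coding mouse genes) is
the right choice on real data, where it approximately equals the observed
universe; the shipped synthetic analysis uses `background="observed"`
(its 2000-gene simulated universe) because using 20000 against a 2000-gene
universe would misstate the null the real-data choice does not.

## Tumor-burden metrics

Caliper volume is the ellipsoid approximation V = π·L·W²/6 with L = max and
W = min of the two axes (the formula squares the width; which caliper axis
is "length" is a convention, so the package normalizes with a warning on
swap). Burden series (volume or radiance) are normalized per subject to a
baseline day (baseline maps to exactly 1; subjects without a baseline are
excluded with a warning); percent change is 100·(v_to − v_from)/v_from;
group summaries report mean ± SD.

## Synthetic data generator

Counts are negative binomial per gene with the mean/dispersion
parameterization (variance μ + μ²α; standard for scRNA-seq and directly
verifiable by moments), means = per-gene baseline × cluster/condition
fold-changes, followed by independent Bernoulli dropout (probability 0.1) —
the simplest mechanism that exercises the 0.1-CPM detection gate. One numpy
`Generator` seeded once drives the whole draw in a fixed order, so
identical (config, seed) gives bit-identical output.

The shipped configuration emulates the structure of a conditional-oncogene
tumor at a desk-scale size of 2000 cells per condition and 2000 genes
(kept deliberately compact so the full pipeline and test suite run in
seconds while every planted effect remains comfortably detectable):

- **15 clusters** spanning tumor (4 subclones), macrophage (2), T cell,
  neutrophil (2), vascular (2), CAF, B cell (2) and dendritic compartments.
  Per-cluster proportions are a free choice (only the total and the pooling
  rule are externally constrained): the T-cell cluster (4) moves 5% → 20%
  between ON and OFF, B cells and CAFs also expand, tumor clusters shrink;
  cluster 9 is kept under 50 cells to exercise pooling.
- **Expression structure**: panel markers at fold 25 in their type's
  clusters over a 0.02-count baseline, 25-gene cell-type programs at fold
  6, pan-immune Ptprc at fold 4 — effect sizes in the range of real marker
  log2FCs (≈2–4.5) and chosen, before any tuning against outcomes, so that
  a specific panel outs-cores the pan-immune panel by more than the 1.2
  annotation margin.
- **Planted interaction**: Il15 in tumor cluster 13 at fold 3 (ON) vs 40
  (OFF) over a 0.005-count baseline; Il2rb constitutive at fold 30 in the
  T-cell cluster. The OFF fold is strong by design — the biology being
  emulated is a strong induction — and sized against the shot-noise
  analysis of decoy pairs: decoy ligands/receptors draw low baselines
  (lognormal, median ≈ 0.004 counts, the regime of real cytokine
  transcripts), whose worst-case sampling deltas in small clusters stay
  several-fold below the planted delta.
- **T-cell positivity**: Cd8a (30% → 50%), Cd69 (15% → 45%) and Ncr1
  (5% → 10%) are bimodal within the T-cell cluster: positive cells express
  at NB mean 2 counts, negatives at the near-zero baseline.
- **QC structure**: 13 `mt-*` genes at baseline 4 counts give a ~5% resting
  mitochondrial fraction; 6% of cells have mito boosted ×4 (≈15%,
  failing the 10% rule) and 3% of cells have their whole mean vector
  scaled ×0.08 (≈90 detected genes, failing the 200-gene rule).
- **Gene sets**: 60 pathways of 50 genes; one contains 80% of the T-cell
  program, the rest are uniform draws.
- **Tumor series**: piecewise log-linear growth/decay with log-normal
  noise; the default regression rate ln(100)/7 per day encodes a 99%
  burden reduction over 7 days.

What the generator does *not* model: ambient RNA, doublets, batch effects,
UMI saturation, realistic gene–gene correlation beyond the planted
programs, or cluster-label noise (labels are emitted as ground truth
because clustering is out of scope). Passing tests therefore demonstrate
that the statistics recover planted effects under an idealized NB/dropout
model — not pipeline performance on real tissue.

## Numerical and engineering choices

- Exact tests ride on scipy (`fisher_exact`, `hypergeom.sf`); the test
  suite checks both against independent integer-combinatorics enumeration
  (to 1e-10/1e-12) rather than trusting either implementation.
- BH via statsmodels `multipletests`; q ≥ p is asserted as an invariant.
- Tie-breaking in outputs is always explicit: stable sorts with documented
  keys (q, then p, then name), sorted gene lists in pooled sets and GMT.
- Degenerate inputs fail loudly and specifically: zero-total cells name the
  QC step, invalid simulation configs name the field, missing predicate
  genes name the gene, dimension mismatches name both files.
- `run_all` wraps each stage so failures name the stage while partial
  outputs remain on disk; the run log records every threshold and the seed
  (no timestamps), and the manifest hashes every output, making
  end-to-end determinism a one-line byte comparison.
- The determinism check and test-suite pipeline runs use 800–2000 cells per
  condition; all results in the README come from the 2000-cell
  configuration with seed 1.
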
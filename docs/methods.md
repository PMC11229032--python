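# Methods

## Problem and data plane

CAR (chimeric antigen receptor) cells kill any cell displaying their
target antigen, so a usable target must be (i) on the cell surface,
(ii) highly expressed across a tumor's cells, and (iii) absent, or
nearly so, from every healthy tissue. `cartarget` operationalizes that
triage on bulk RNA-seq expression: TCGA-style tumor cohorts (primary
tumor, metastatic, adjacent-normal samples), GTEx-style healthy-tissue
baselines, and a CCLE/DepMap-style cell-line panel for picking wet-lab
validation lines.

All computation runs on gene × sample matrices of TPM. Three on-disk
encodings are supported and declared explicitly — linear TPM,
log2(TPM+1), and the Xena RSEM encoding log2(TPM+0.001) — and every
conversion routes through linear TPM, clamping at zero so that the
Xena zero sentinel (−9.966) decodes to exactly 0 TPM. Because TCGA
cohorts carry very few adjacent normals, the control group for a tumor
pools its adjacent normals with the GTEx tissues assigned by an
editable cohort map (`data/default_cohort_map.tsv`, transcribed from
the standard TCGA→GTEx tissue correspondence; tumors such as HNSC or
MESO with no clean tissue counterpart map to adjacent normals only).

## Statistics

For each gene, with tumor values T and control values C (TPM):

* **Fold change** `FC = (median(T) + ε) / (median(C) + ε)` with
  ε = 0.01 TPM. The symmetric pseudocount keeps the ratio finite and
  positive when a median is zero and preserves the reciprocal identity
  FC(a,b)·FC(b,a) = 1 exactly.
* **log2 fold change** = `median(log2(T+1)) − median(log2(C+1))` — the
  difference of log-scale medians, *not* log2 of the FC ratio; the two
  deliberately disagree on skewed groups and both are reported.
* **Significance**: two-sided Mann–Whitney U. The exact null
  distribution is used when `min(n, m) ≤ 8` and the pooled sample is
  tie-free; otherwise the tie-corrected normal approximation with
  continuity correction. An all-identical pooled sample returns p = 1.
  Because the test is rank-based, p-values are invariant under the
  TPM ↔ log2(TPM+1) transform.
* **Multiple testing**: Benjamini–Hochberg, applied over *every* gene
  tested in a call (the full surfaceome universe for the screen, all
  tissues for the tissue comparison, the three pairs for the
  three-group comparison), never over the reported subset only.
  Significance is adjusted p < 0.05.

The antigen screen reports genes with adjusted p < 0.05 and
FC ≥ threshold (overexpressed; CAR candidates) or FC ≤ 1/threshold
(underexpressed; NOT-gate candidates), sorted by |log2FC| descending
with ties broken by symbol, and floors adjusted p at 1e−300 before
−log10 so volcano coordinates stay finite. Metastatic samples are
excluded from all tests except the per-cohort median profile and the
dedicated three-group (metastatic / primary / control) comparison,
whose melanoma use case is the one cohort with enough metastatic
samples to test.

## Logic-gate feasibility

The dual-antigen assessment has two parts. Pair correlation reports
Pearson and Spearman coefficients of the two genes, separately in
tumor and control samples, computed on log2(TPM+1) (Pearson on raw TPM
is outlier-dominated; Spearman is scale-free either way). A constant
gene makes the coefficient undefined and it is reported as NaN, never
coerced to 0.

The feasibility classifier is an explicit formalization of a judgement
usually made visually, with all thresholds exposed in `GateConfig`:
an antigen is "on" at TPM ≥ τ_on (default 10) and "absent" below
τ_off (default 1); tumor coverage must reach c_min (default 0.8) and
no single healthy tissue may exceed co-coverage s_max (default 0.05).
The defaults are design choices on the order of the expression levels
the selector workflow uses (hundreds of TPM in tumors, an "on"
threshold an order of magnitude above typical background); they are
deliberately conservative and meant to be tuned per program.

* AND: tumor both-on fraction ≥ c_min and every tissue both-on ≤ s_max.
* OR: tumor either-on ≥ c_min and every tissue either-on ≤ s_max.
* NOT (a activating, b inhibitory): tumor fraction(a on, b absent)
  ≥ c_min, and in every tissue where a alone would trigger
  (on-fraction > s_max) the veto antigen b is present (≥ τ_off) in
  ≥ 1 − s_max of samples.
* IF-BETTER: AND failed only on tumor coverage, a alone covers
  ≥ c_min, and b is co-stimulatory (on) in ≥ c_min/2 of tumors.

AND and OR are symmetric in the gene pair; NOT and IF-BETTER are
direction-specific. Raising τ_on can never increase a coverage
fraction (property-tested), and every fraction equals a per-sample
count.

## Cell-line selection

`select_cell_lines` filters a DepMap-shaped panel by a TPM threshold,
optionally within one lineage, sorted by expression descending.
"Above" means ≥ threshold and "below" means < threshold, so the two
directions partition the panel at any threshold. The DepMap loader
accepts the release orientation (models × genes, log2(TPM+1), symbols
suffixed with Entrez ids) and converts to the package's gene × sample
TPM orientation.

## Synthetic data

The generator (`cartarget.simulate`) emulates the *structure* of the
real inputs: a tumor cohort with the three TCGA sample classes, named
GTEx control tissues, a gene universe standing in for the surfaceome,
and a DepMap-style panel with metadata — written to disk in exactly
the dialects the loaders read.

Model: per gene, baseline `b_g ~ Uniform[0, 8]` on the log2(TPM+1)
scale (≈ 1–255 TPM, the dynamic range the tools exercise); each sample
of class c draws `TPM = max(0, 2^(b_g + s_{g,c} + N(0, σ²)) − 1)`,
with `s_{g,c} = log2(FC)` for planted (gene, class) or (gene, tissue)
effects and 0 otherwise. Log-normal variation on the log scale is used
instead of count-level (negative-binomial) noise because the toolkit
consumes TPM matrices, never raw counts. Defaults are the package's
benchmark study conditions: 6000 genes, 40 primary tumors vs 40 pooled
controls (10 adjacent normals + 30 of one tissue), σ = 0.25.

What the generator does **not** emulate: gene–gene covariance,
library-size and batch artifacts, heavy-tailed per-gene dispersion,
and the ~20 % zero-inflation of real RSEM output. Passing the planted
benchmarks therefore demonstrates that the pipeline's statistics and
bookkeeping are correct, not that real TCGA screens will achieve the
same recall/FDR.

## Benchmarks computed by `scripts/acceptance.py`

* Planted-signal recovery: 6000 genes, 3 planted at 16-fold, 40 vs 40,
  σ = 0.25, screened at 15-fold over 20 seeds; recall and empirical
  FDR are reported (target: recall ≥ 0.95, FDR ≤ 0.05). The handful of
  missed calls at this setting come from genes whose measured FC lands
  marginally under the 15-fold filter, not from failed significance.
* Null calibration: the same cohort with nothing planted; the worst
  per-seed fraction of genes at adjusted p < 0.05 (3 seeds).
* Zero-noise recovery: at σ = 0 the planted 16-fold effect is
  recovered exactly (up to the ε = 0.01 pseudocount).
* Exact worked examples: Mann–Whitney p([1,2] vs [3,4]) = 1/3,
  BH([.01,.02,.03,.04]) = [.04]×4; fold-change reciprocal and log2FC
  antisymmetry maximum error over 1000 random group pairs.
* The gate toy (tumor A=B=100 TPM; one tissue A=100, B=0): AND viable,
  OR not.
* The three-tier cell-line panel (1270 / 635 / 241 TPM): 3 lines pass
  200 TPM, 1 passes 700 TPM.

## Numerical and interface conventions

* All primary outputs are TSV with frozen column order and floats at 6
  significant digits; identical inputs and seeds reproduce files
  byte-for-byte (tested per CLI subcommand).
* Duplicate gene rows (on load, or symbol collisions after id mapping)
  keep the row with the highest total expression — deterministic and
  favoring the dominant transcript; drops are counted in the run log.
  Unmapped ids are dropped rather than kept under their original keys,
  since downstream gene-set filtering is symbol-keyed.
* Sort ties everywhere break by gene/cell-line name ascending using
  stable sorts.
* Each CLI run writes `<out>.runlog.json` with the package version,
  parameters, SHA-256 digests of all inputs and bookkeeping counts; no
  timestamps, so reruns are reproducible.

## Known limitations

Gene-level expression only: no isoform or post-translational
information, although surface antigen recognition can depend on both.
The gate classifier treats samples as exchangeable and uses hard TPM
thresholds; it does not model single-cell heterogeneity within a
sample. The shipped cohort map is a sensible default, not a curated
clinical pairing — revise it per study.
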
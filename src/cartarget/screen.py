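"""Expression-profiling tools for target discovery.

Five batch tools built on the shared statistics:

* :func:`screen_taa` — genome-wide (surfaceome-restricted) screen for
  antigens over- or under-expressed in primary tumor vs control, the
  volcano-table view;
* :func:`fc_table` — fold change of chosen genes across chosen tumors,
  for judging whether a candidate is tumor-specific or pan-tumor;
* :func:`median_profile` — per-cohort median expression of one gene in
  primary / metastatic / control groups;
* :func:`tissue_expression` — one gene across all GTEx tissues,
  optionally each tissue tested against a tumor's primary samples to
  flag off-tumor expression;
* :func:`skcm_compare` — the melanoma three-group comparison
  (metastatic vs primary vs control), the one cohort with enough
  metastatic samples to test.

Metastatic samples are excluded from every statistic except the median
profile and the melanoma comparison; their group sizes are otherwise
too small to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CartargetError
from .io import Cohort, CohortMap, GeneSet, SampleAnnotation, SampleClass, build_cohort
from .matrix import ExpressionMatrix
from .stats import (
    FC_PSEUDOCOUNT,
    SIGNIFICANCE_LEVEL,
    adjust_pvalues,
    fold_change,
    log2_fold_change,
    mwu_test,
    mwu_test_rows,
)

__all__ = [
    "ScreenResult",
    "SkcmResult",
    "screen_taa",
    "fc_table",
    "median_profile",
    "tissue_expression",
    "skcm_compare",
]

#: Floor applied to adjusted p before -log10, keeping volcano y finite.
ADJ_P_FLOOR = 1e-300

VOLCANO_COLUMNS = [
    "gene", "n_tumor", "n_control",
    "tumor_median_tpm", "control_median_tpm",
    "tumor_median_log2", "control_median_log2",
    "fc", "log2fc", "p_value", "adj_p", "significant", "neg_log10_adj_p",
]


@dataclass
class ScreenResult:
    """Outcome of one tumor-associated-antigen screen.

    ``table`` holds only the reported rows (significant and past the
    fold-change threshold, sorted by |log2FC| descending); ``universe``
    holds every gene tested, i.e. the family the adjustment ran over.
    """

    tumor_code: str
    direction: str
    fc_threshold: float
    table: pd.DataFrame
    universe: pd.DataFrame

    @property
    def universe_size(self) -> int:
        return int(self.universe.shape[0])


@dataclass
class SkcmResult:
    """Three-group comparison output: per-class summaries + pairwise tests."""

    gene: str
    summaries: pd.DataFrame
    pairwise: pd.DataFrame


def _sorted_report(df: pd.DataFrame) -> pd.DataFrame:
    # |log2fc| descending, ties broken by gene symbol ascending — frozen
    # so outputs are byte-reproducible.
    key = df.assign(_abs=df["log2fc"].abs())
    key = key.sort_values(["_abs", "gene"], ascending=[False, True], kind="mergesort")
    return key.drop(columns="_abs").reset_index(drop=True)


def screen_taa(
    cohort: Cohort,
    gene_universe: GeneSet | None = None,
    fc_threshold: float = 2.0,
    direction: str = "over",
) -> ScreenResult:
    """Screen every gene for tumor-vs-control differential expression.

    Each gene in the (optionally gene-set-restricted) universe gets a
    fold change, log2 fold change and two-sided Mann–Whitney p; BH
    adjustment runs across the whole tested universe, never just the
    reported rows.  Reported rows satisfy ``adj_p < 0.05`` and
    ``FC ≥ threshold`` (over) or ``FC ≤ 1/threshold`` (under).
    """
    if fc_threshold <= 1:
        raise CartargetError("fc_threshold must be > 1")
    if direction not in ("over", "under"):
        raise CartargetError(f"direction must be 'over' or 'under', got {direction!r}")
    genes = list(cohort.matrix.data.index)
    if gene_universe is not None:
        genes = [g for g in genes if g in gene_universe.symbols]
        if not genes:
            raise CartargetError(
                f"gene universe {gene_universe.name!r} is empty after filtering"
            )
    T = cohort.block(genes, "primary_tumor")
    C = cohort.block(genes, "control")
    if T.shape[1] < 2 or C.shape[1] < 2:
        raise CartargetError("screen needs at least 2 samples per group")

    med_t = np.median(T, axis=1)
    med_c = np.median(C, axis=1)
    fc = (med_t + FC_PSEUDOCOUNT) / (med_c + FC_PSEUDOCOUNT)
    log_t = np.median(np.log2(T + 1.0), axis=1)
    log_c = np.median(np.log2(C + 1.0), axis=1)
    log2fc = log_t - log_c
    p = mwu_test_rows(T, C)
    adj = adjust_pvalues(p)
    significant = adj < SIGNIFICANCE_LEVEL

    universe = pd.DataFrame({
        "gene": genes,
        "n_tumor": T.shape[1],
        "n_control": C.shape[1],
        "tumor_median_tpm": med_t,
        "control_median_tpm": med_c,
        "tumor_median_log2": log_t,
        "control_median_log2": log_c,
        "fc": fc,
        "log2fc": log2fc,
        "p_value": p,
        "adj_p": adj,
        "significant": significant,
        "neg_log10_adj_p": -np.log10(np.maximum(adj, ADJ_P_FLOOR)),
    })[VOLCANO_COLUMNS]

    if direction == "over":
        passing = significant & (fc >= fc_threshold)
    else:
        passing = significant & (fc <= 1.0 / fc_threshold)
    table = _sorted_report(universe.loc[passing])
    return ScreenResult(cohort.tumor_code, direction, float(fc_threshold), table, universe)


def fc_table(
    genes: Sequence[str],
    tumor_codes: Sequence[str],
    scale: str,
    tcga_m: ExpressionMatrix,
    gtex_m: ExpressionMatrix,
    annotations: Iterable[SampleAnnotation],
    cmap: CohortMap,
) -> pd.DataFrame:
    """Fold change (or log2FC) of each gene across each selected tumor.

    Rows = genes, columns = tumor codes.  ``scale`` is ``"fc"`` (median
    TPM ratio) or ``"log2fc"`` (difference of log-scale medians; this is
    *not* log2 of the ratio and diverges from it on skewed groups).
    """
    scale = scale.lower()
    if scale not in ("fc", "log2fc"):
        raise CartargetError(f"scale must be 'fc' or 'log2fc', got {scale!r}")
    known = set(tcga_m.data.index) & set(gtex_m.data.index)
    bad_genes = [g for g in genes if g not in known]
    bad_tumors = [t for t in tumor_codes if t not in cmap]
    if bad_genes or bad_tumors:
        raise CartargetError(
            f"unknown genes {bad_genes} / unknown tumors {bad_tumors}"
        )
    anns = list(annotations)
    out = pd.DataFrame(index=pd.Index(list(genes), name="gene"),
                       columns=list(tumor_codes), dtype=float)
    for code in tumor_codes:
        cohort = build_cohort(code, tcga_m, gtex_m, anns, cmap)
        for g in genes:
            t = cohort.class_values(g, "primary_tumor")
            c = cohort.class_values(g, "control")
            out.loc[g, code] = (
                fold_change(t, c) if scale == "fc" else log2_fold_change(t, c)
            )
    return out


def median_profile(
    gene: str,
    tcga_m: ExpressionMatrix,
    gtex_m: ExpressionMatrix,
    annotations: Iterable[SampleAnnotation],
    cmap: CohortMap,
    tumor_codes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Median expression of one gene per cohort × sample class.

    One row per (tumor, class) among primary_tumor / metastatic /
    control; cohorts without metastatic samples omit that row.
    """
    anns = list(annotations)
    codes = list(tumor_codes) if tumor_codes else sorted(
        {a.cohort_code for a in anns
         if a.source_project == "TCGA" and a.cohort_code in cmap}
    )
    rows = []
    for code in codes:
        cohort = build_cohort(code, tcga_m, gtex_m, anns, cmap)
        for cls, ids in (
            ("primary_tumor", cohort.primary_ids),
            ("metastatic", cohort.metastatic_ids),
            ("control", cohort.control_ids),
        ):
            if not ids:
                continue
            v = cohort.matrix.data.loc[gene, ids].to_numpy(dtype=float) \
                if gene in cohort.matrix.data.index else None
            if v is None:
                raise CartargetError(f"gene {gene!r} not present in cohort {code}")
            rows.append({
                "tumor": code,
                "group": cls,
                "n": len(ids),
                "median_tpm": float(np.median(v)),
                "median_log2": float(np.median(np.log2(v + 1.0))),
            })
    return pd.DataFrame(rows, columns=["tumor", "group", "n", "median_tpm", "median_log2"])


def tissue_expression(
    gene: str,
    gtex_m: ExpressionMatrix,
    annotations: Iterable[SampleAnnotation],
    cohort: Cohort | None = None,
) -> pd.DataFrame:
    """One gene across all GTEx tissues, optionally tested against a tumor.

    Without a cohort the table is descriptive (n, medians per tissue).
    With a cohort, a leading row summarizes the tumor's primary samples
    and every tissue is Mann–Whitney-tested against them, with BH over
    the tissues tested in this call; log2FC is tumor − tissue.
    """
    from .matrix import tpm_frame

    if gene not in gtex_m.data.index:
        raise CartargetError(f"gene {gene!r} not present in GTEx matrix")
    gtex_tpm = tpm_frame(gtex_m)
    by_tissue: dict = {}
    sample_set = set(gtex_m.sample_ids)
    for a in annotations:
        if a.source_project == "GTEX" and a.sample_id in sample_set:
            by_tissue.setdefault(a.cohort_code, []).append(a.sample_id)
    if not by_tissue:
        raise CartargetError("no annotated GTEx samples found in matrix")

    tumor_vals = None
    rows = []
    if cohort is not None:
        tumor_vals = cohort.class_values(gene, "primary_tumor")
        rows.append({
            "group": f"{cohort.tumor_code} primary tumor",
            "n": tumor_vals.size,
            "median_tpm": float(np.median(tumor_vals)),
            "median_log2": float(np.median(np.log2(tumor_vals + 1.0))),
            "log2fc": np.nan, "p_value": np.nan, "adj_p": np.nan,
            "significant": False,
        })
    pvals = []
    tissue_rows = []
    for tissue in sorted(by_tissue):
        v = gtex_tpm.loc[gene, by_tissue[tissue]].to_numpy(dtype=float)
        row = {
            "group": tissue,
            "n": v.size,
            "median_tpm": float(np.median(v)),
            "median_log2": float(np.median(np.log2(v + 1.0))),
            "log2fc": np.nan, "p_value": np.nan, "adj_p": np.nan,
            "significant": False,
        }
        if tumor_vals is not None:
            row["log2fc"] = log2_fold_change(tumor_vals, v)
            row["p_value"] = mwu_test(tumor_vals, v)
            pvals.append(row["p_value"])
        tissue_rows.append(row)
    if tumor_vals is not None and pvals:
        adj = adjust_pvalues(pvals)
        for row, a in zip(tissue_rows, adj):
            row["adj_p"] = float(a)
            row["significant"] = bool(a < SIGNIFICANCE_LEVEL)
    rows.extend(tissue_rows)
    cols = ["group", "n", "median_tpm", "median_log2",
            "log2fc", "p_value", "adj_p", "significant"]
    df = pd.DataFrame(rows, columns=cols)
    if cohort is None:
        df = df.drop(columns=["log2fc", "p_value", "adj_p", "significant"])
    return df


def skcm_compare(gene: str, cohort: Cohort) -> SkcmResult:
    """Melanoma-style three-group comparison for one gene.

    Requires non-empty metastatic, primary tumor and control groups;
    runs the three pairwise Mann–Whitney tests with BH over those three
    p-values and reports per-class summaries.
    """
    groups = {
        "metastatic": cohort.metastatic_ids,
        "primary_tumor": cohort.primary_ids,
        "control": cohort.control_ids,
    }
    for name, ids in groups.items():
        if not ids:
            raise CartargetError(f"class {name!r} is empty in cohort {cohort.tumor_code}")
    values = {name: cohort.class_values(gene, name) for name in groups}
    summaries = pd.DataFrame([
        {
            "group": name,
            "n": v.size,
            "median_tpm": float(np.median(v)),
            "median_log2": float(np.median(np.log2(v + 1.0))),
        }
        for name, v in values.items()
    ], columns=["group", "n", "median_tpm", "median_log2"])

    pairs = [
        ("metastatic", "primary_tumor"),
        ("metastatic", "control"),
        ("primary_tumor", "control"),
    ]
    rows = []
    for a, b in pairs:
        rows.append({
            "group_a": a,
            "group_b": b,
            "log2fc": log2_fold_change(values[a], values[b]),
            "p_value": mwu_test(values[a], values[b]),
        })
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "log2fc", "p_value"])
    pairwise["adj_p"] = adjust_pvalues(pairwise["p_value"].to_numpy())
    pairwise["significant"] = pairwise["adj_p"] < SIGNIFICANCE_LEVEL
    return SkcmResult(gene, summaries, pairwise)
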
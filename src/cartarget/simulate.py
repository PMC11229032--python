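"""Synthetic TCGA/GTEx/CCLE-shaped cohorts with planted signals.

The generator emulates the structure of the real inputs — a tumor
cohort with primary / metastatic / adjacent-normal samples, GTEx
control tissues, a surface gene set, and a DepMap-style cell-line panel
— so every tool is testable end to end without downloads.

Model: each gene g draws a baseline b_g ~ Uniform[0, 8] on the
log2(TPM+1) scale (≈ 0–255 TPM, the dynamic range the tools exercise);
a sample of class c gets

    TPM = max(0, 2^(b_g + s_{g,c} + N(0, σ²)) − 1)

where the class shift s_{g,c} = log2(FC) for planted (gene, class)
pairs and 0 otherwise.  Log-normal variation on the log scale is used
rather than count-level noise because the toolkit consumes TPM
matrices, never raw counts.  Every planted effect is recorded in a
truth table, and generation is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CartargetError, ValidationError
from .io import CohortMap, GeneSet, SampleAnnotation, SampleClass
from .matrix import ExpressionMatrix, Scale, convert_scale

__all__ = [
    "PlantedSignal",
    "CohortSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_celllines",
    "write_cohort",
    "write_celllines",
]

FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class PlantedSignal:
    """One planted effect: ``target`` is a tumor sample class
    ("primary_tumor" or "metastatic") or "tissue:<name>" for a
    tissue-restricted pattern; ``fold_change`` multiplies the baseline
    (log2 shift of log2(FC))."""

    gene: "int | str"
    target: str
    fold_change: float

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValidationError("planted fold change must be > 0")
        ok = self.target in ("primary_tumor", "metastatic") or self.target.startswith("tissue:")
        if not ok:
            raise ValidationError(f"unknown planted target {self.target!r}")


@dataclass
class CohortSpec:
    """Study conditions for one simulated tumor cohort.

    Defaults mirror the screening benchmark this package is validated
    on: 6000 surface genes, 40 primary tumors vs 40 pooled controls
    (10 adjacent normals + 30 GTEx Colon), log-normal noise σ = 0.25 on
    the log2 scale, baselines uniform in [0, 8].
    """

    seed: int
    tumor_code: str = "COAD"
    n_primary: int = 40
    n_metastatic: int = 0
    n_adjacent_normal: int = 10
    tissues: Mapping[str, int] = field(default_factory=lambda: {"Colon": 30})
    n_genes: int = 6000
    planted: Sequence[PlantedSignal] = ()
    sigma: float = 0.25
    baseline_range: tuple = (0.0, 8.0)

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("CohortSpec.seed is mandatory")
        for n in (self.n_primary, self.n_metastatic, self.n_adjacent_normal):
            if n < 0:
                raise ValidationError("sample sizes must be >= 0")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        self.planted = [
            p if isinstance(p, PlantedSignal) else PlantedSignal(*p)
            for p in self.planted
        ]


@dataclass
class SimulatedCohort:
    """Everything the loaders would produce, plus the planted truth."""

    tcga: ExpressionMatrix  # TPM; primary + metastatic + adjacent normals
    gtex: ExpressionMatrix  # TPM; tissue samples
    annotations: list
    cohort_map: CohortMap
    gene_set: GeneSet
    truth: pd.DataFrame  # gene, target, fold_change


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def _resolve_gene(g, n_genes: int) -> str:
    if isinstance(g, (int, np.integer)):
        if not 0 <= g < n_genes:
            raise CartargetError(f"planted gene index {g} out of range [0, {n_genes})")
        return _gene_name(int(g))
    return str(g)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate one tumor cohort plus its GTEx control tissues."""
    rng = np.random.default_rng(spec.seed)
    genes = [_gene_name(i) for i in range(spec.n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}

    shifts: dict = {}
    truth_rows = []
    for p in spec.planted:
        gname = _resolve_gene(p.gene, spec.n_genes)
        if gname not in gene_index:
            raise CartargetError(f"planted gene {gname!r} not among generated genes")
        shifts[(gname, p.target)] = np.log2(p.fold_change)
        truth_rows.append({"gene": gname, "target": p.target,
                           "fold_change": p.fold_change})

    baseline = rng.uniform(*spec.baseline_range, size=spec.n_genes)

    def block(class_key: str, n: int) -> np.ndarray:
        shift = np.zeros(spec.n_genes)
        for (gname, target), s in shifts.items():
            if target == class_key:
                shift[gene_index[gname]] += s
        log2v = baseline[:, None] + shift[:, None]
        if spec.sigma > 0:
            log2v = log2v + rng.normal(0.0, spec.sigma, size=(spec.n_genes, n))
        else:
            log2v = np.broadcast_to(log2v, (spec.n_genes, n)).copy()
        return np.maximum(np.exp2(log2v) - 1.0, 0.0)

    tcga_cols, tcga_blocks, annotations = [], [], []
    code = spec.tumor_code
    for cls, class_key, n, prefix in (
        (SampleClass.PRIMARY_TUMOR, "primary_tumor", spec.n_primary, "PT"),
        (SampleClass.METASTATIC, "metastatic", spec.n_metastatic, "MET"),
        (SampleClass.ADJACENT_NORMAL, "adjacent_normal", spec.n_adjacent_normal, "NT"),
    ):
        if n == 0:
            continue
        ids = [f"{code}-{prefix}-{i:03d}" for i in range(n)]
        tcga_cols.extend(ids)
        tcga_blocks.append(block(class_key, n))
        annotations.extend(
            SampleAnnotation(s, "TCGA", code, cls) for s in ids
        )

    gtex_cols, gtex_blocks = [], []
    for tissue, n in spec.tissues.items():
        if n == 0:
            continue
        ids = [f"GTEX-{tissue.replace(' ', '')}-{i:03d}" for i in range(n)]
        gtex_cols.extend(ids)
        gtex_blocks.append(block(f"tissue:{tissue}", n))
        annotations.extend(
            SampleAnnotation(s, "GTEX", tissue, SampleClass.GTEX_NORMAL) for s in ids
        )

    if not tcga_cols:
        raise CartargetError("cohort spec generates no TCGA samples")
    tcga = ExpressionMatrix(
        pd.DataFrame(np.concatenate(tcga_blocks, axis=1) if tcga_blocks else
                     np.empty((spec.n_genes, 0)),
                     index=genes, columns=tcga_cols),
        Scale.TPM,
    )
    gtex = ExpressionMatrix(
        pd.DataFrame(np.concatenate(gtex_blocks, axis=1) if gtex_blocks else
                     np.empty((spec.n_genes, 0)),
                     index=genes, columns=gtex_cols),
        Scale.TPM,
    )
    cmap = CohortMap({code: set(t for t, n in spec.tissues.items() if n > 0)})
    gene_set = GeneSet("simulated_surfaceome", set(genes))
    truth = pd.DataFrame(truth_rows, columns=["gene", "target", "fold_change"])
    return SimulatedCohort(tcga, gtex, annotations, cmap, gene_set, truth)


def simulate_celllines(
    n_genes: int,
    lineages: Mapping[str, "int | Sequence[str]"],
    planted: Sequence[tuple],
    seed: int,
):
    """Generate a DepMap-shaped cell-line panel.

    ``lineages`` maps lineage name → line count (auto names) or an
    explicit list of cell-line names.  ``planted`` entries are
    (gene, line_name_or_lineage, tpm_level): the named line (or every
    line of the lineage) expresses the gene at exactly that TPM.
    Returns the gene × line TPM matrix and the model-metadata table.
    """
    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(n_genes)]
    planted_genes = [str(p[0]) for p in planted]
    for g in planted_genes:
        if g not in set(genes):
            genes.append(g)

    lines, line_lineage = [], {}
    for lineage, spec in lineages.items():
        names = (
            [f"{lineage.upper()}-{i + 1:02d}" for i in range(spec)]
            if isinstance(spec, int) else [str(s) for s in spec]
        )
        for name in names:
            if name in line_lineage:
                raise CartargetError(f"duplicate cell-line name {name!r}")
            line_lineage[name] = lineage
            lines.append(name)

    values = np.maximum(
        np.exp2(rng.uniform(0.0, 8.0, size=(len(genes), len(lines)))) - 1.0, 0.0
    ) if lines else np.empty((len(genes), 0))
    gene_idx = {g: i for i, g in enumerate(genes)}
    line_idx = {l: i for i, l in enumerate(lines)}
    for gene, where, level in planted:
        gene = str(gene)
        targets = (
            [where] if where in line_idx
            else [l for l in lines if line_lineage[l] == where]
        )
        if not targets:
            raise CartargetError(f"planted target {where!r} matches no line or lineage")
        for l in targets:
            values[gene_idx[gene], line_idx[l]] = float(level)

    model_ids = [f"SIM-{i + 1:06d}" for i in range(len(lines))]
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=model_ids), Scale.TPM
    )
    models = pd.DataFrame({
        "model_id": model_ids,
        "cell_line_name": lines,
        "lineage": [line_lineage[l] for l in lines],
        "primary_disease": [f"{line_lineage[l]} cancer" for l in lines],
        "subtype": ["simulated" for _ in lines],
        "catalog_number": [f"CAT-{i + 1:04d}" for i in range(len(lines))],
    })
    return expression, models


# ---------------------------------------------------------------------------
# on-disk fixtures in the exact dialects the loaders read


def _write_matrix(m: ExpressionMatrix, path: Path) -> None:
    df = m.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_cohort(sim: SimulatedCohort, outdir) -> dict:
    """Write a simulated cohort as the TSV files the loaders consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in {
        "tcga_expr": "tcga_expr.tsv",
        "gtex_expr": "gtex_expr.tsv",
        "tcga_pheno": "tcga_pheno.tsv",
        "gtex_pheno": "gtex_pheno.tsv",
        "cohort_map": "cohort_map.tsv",
        "gene_set": "geneset.txt",
        "truth": "truth.tsv",
    }.items()}
    _write_matrix(sim.tcga, paths["tcga_expr"])
    _write_matrix(sim.gtex, paths["gtex_expr"])

    inv_class = {
        SampleClass.PRIMARY_TUMOR: "Primary Tumor",
        SampleClass.METASTATIC: "Metastatic",
        SampleClass.ADJACENT_NORMAL: "Solid Tissue Normal",
    }
    tcga_rows = [
        {"sample": a.sample_id, "sample_type": inv_class[a.sample_class],
         "cohort": a.cohort_code}
        for a in sim.annotations if a.source_project == "TCGA"
    ]
    pd.DataFrame(tcga_rows, columns=["sample", "sample_type", "cohort"]).to_csv(
        paths["tcga_pheno"], sep="\t", index=False
    )
    gtex_rows = [
        {"sample": a.sample_id, "tissue": a.cohort_code}
        for a in sim.annotations if a.source_project == "GTEX"
    ]
    pd.DataFrame(gtex_rows, columns=["sample", "tissue"]).to_csv(
        paths["gtex_pheno"], sep="\t", index=False
    )
    with open(paths["cohort_map"], "wt", encoding="utf-8") as fh:
        for code, tissues in sorted(sim.cohort_map.entries.items()):
            fh.write(f"{code}\t{','.join(sorted(tissues))}\n")
    with open(paths["gene_set"], "wt", encoding="utf-8") as fh:
        for g in sorted(sim.gene_set.symbols):
            fh.write(g + "\n")
    sim.truth.to_csv(paths["truth"], sep="\t", index=False, float_format=FLOAT_FORMAT)
    return {k: str(v) for k, v in paths.items()}


def write_celllines(expression: ExpressionMatrix, models: pd.DataFrame, outdir) -> dict:
    """Write a simulated panel in the DepMap dialect (models × genes,
    log2(TPM+1)) plus its model table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = outdir / "ccle_expr.tsv"
    model_path = outdir / "model.tsv"
    logm = convert_scale(expression, Scale.LOG2_TPM_PLUS_1)
    df = logm.data.T
    df.index.name = "model_id"
    df.to_csv(expr_path, sep="\t", float_format=FLOAT_FORMAT)
    models.to_csv(model_path, sep="\t", index=False)
    return {"ccle_expr": str(expr_path), "model": str(model_path)}
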
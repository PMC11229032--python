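"""Loading and harmonizing TCGA/GTEx/CCLE-shaped inputs.

The loaders accept the plain-text dialects of the public resources the
toolkit was built around:

* expression: tab-separated gene × sample matrices (first column gene
  id) with a caller-declared scale — linear TPM, log2(TPM+1), or the
  Xena RSEM encoding log2(TPM+0.001);
* phenotype: Xena-style TCGA and GTEx sample tables and DepMap-style
  cell-line model tables, normalized to :class:`SampleAnnotation`;
* a tumor → control-tissue pairing map (which GTEx tissues supplement
  the sparse TCGA adjacent normals for each tumor);
* a surface gene set (one symbol per line), used to restrict screens to
  CAR-targetable plasma-membrane genes.

``build_cohort`` assembles the per-tumor analysis unit: primary tumor
samples, metastatic samples when present, and the pooled control group
(adjacent normals plus the mapped GTEx tissues).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CartargetError, ParseError, ValidationError
from .matrix import ExpressionMatrix, Scale, convert_scale

logger = logging.getLogger(__name__)

__all__ = [
    "SampleClass",
    "SampleAnnotation",
    "CohortMap",
    "GeneSet",
    "Cohort",
    "load_expression",
    "load_phenotype",
    "load_cohort_map",
    "default_cohort_map",
    "load_gene_set",
    "map_gene_ids",
    "filter_gene_set",
    "build_cohort",
]


class SampleClass(str, enum.Enum):
    PRIMARY_TUMOR = "primary_tumor"
    METASTATIC = "metastatic"
    ADJACENT_NORMAL = "adjacent_normal"
    GTEX_NORMAL = "gtex_normal"
    CELL_LINE = "cell_line"


@dataclass(frozen=True)
class SampleAnnotation:
    """One sample's project, cohort and class labels."""

    sample_id: str
    source_project: str  # TCGA | GTEX | CCLE
    cohort_code: str  # tumor abbreviation, GTEx tissue, or lineage
    sample_class: SampleClass

    def __post_init__(self):
        if self.source_project == "GTEX" and self.sample_class is not SampleClass.GTEX_NORMAL:
            raise ValidationError("GTEX samples must be class gtex_normal")
        if self.sample_class is SampleClass.GTEX_NORMAL and self.source_project != "GTEX":
            raise ValidationError("gtex_normal class requires source GTEX")
        if (self.source_project == "CCLE") != (self.sample_class is SampleClass.CELL_LINE):
            raise ValidationError("cell_line class iff source CCLE")


@dataclass
class CohortMap:
    """Tumor code → GTEx control tissues used to supplement adjacent normals."""

    entries: dict

    def __post_init__(self):
        self.entries = {str(k): set(v) for k, v in self.entries.items()}

    def tissues_for(self, tumor_code: str) -> set:
        if tumor_code not in self.entries:
            raise CartargetError(
                f"tumor code {tumor_code!r} absent from cohort map "
                f"(known: {sorted(self.entries)[:8]}...)"
            )
        return set(self.entries[tumor_code])

    def __contains__(self, tumor_code: str) -> bool:
        return tumor_code in self.entries


@dataclass
class GeneSet:
    """A named set of gene symbols (e.g. the GO:0005886 surfaceome)."""

    name: str
    symbols: set

    def __post_init__(self):
        self.symbols = set(map(str, self.symbols))
        if not self.symbols:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass
class Cohort:
    """One tumor's analysis unit: merged TPM matrix plus sample-id sets.

    The three sets are disjoint; ``control`` pools TCGA adjacent normals
    with the mapped GTEx tissues.  ``control_tissue`` records, for each
    control sample, which tissue (or "adjacent_normal") it came from.
    """

    tumor_code: str
    matrix: ExpressionMatrix  # TPM scale, columns = all cohort samples
    primary_ids: list
    metastatic_ids: list
    control_ids: list
    control_tissue: dict = field(default_factory=dict)

    def class_values(self, gene: str, which: str) -> np.ndarray:
        ids = {
            "primary_tumor": self.primary_ids,
            "metastatic": self.metastatic_ids,
            "control": self.control_ids,
        }[which]
        if gene not in self.matrix.data.index:
            raise CartargetError(f"gene {gene!r} not present in cohort matrix")
        return self.matrix.data.loc[gene, ids].to_numpy(dtype=float)

    def block(self, genes: Sequence[str], which: str) -> np.ndarray:
        ids = {
            "primary_tumor": self.primary_ids,
            "metastatic": self.metastatic_ids,
            "control": self.control_ids,
        }[which]
        return self.matrix.data.loc[list(genes), ids].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# expression


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CartargetError(f"input file not found: {path}")
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if not header or "\t" not in header:
        raise ParseError(
            f"{path}: malformed header line (expected tab-separated "
            f"'gene<TAB>sample...'): {header[:80]!r}"
        )
    cols = header.split("\t")
    samples = cols[1:]
    seen = set()
    for s in samples:
        if s in seen:
            raise ParseError(f"{path}: duplicate sample column {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df


def _numeric_or_report(df: pd.DataFrame, path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at "
                f"gene {gene!r}, sample {col!r}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy().argmax()]
            raise ParseError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def _collapse_duplicate_genes(df: pd.DataFrame) -> tuple:
    """Keep, per duplicated gene id, the row with the highest total expression."""
    if not df.index.has_duplicates:
        return df, 0
    totals = df.sum(axis=1).to_numpy()
    order = np.argsort(-totals, kind="stable")
    ranked = df.iloc[order]
    kept = ranked[~ranked.index.duplicated(keep="first")]
    kept = kept.loc[pd.unique(df.index)]  # restore first-seen gene order
    return kept, int(df.shape[0] - kept.shape[0])


def load_expression(path, dialect: "str | Scale") -> ExpressionMatrix:
    """Load a tab-separated gene × sample matrix with a declared scale.

    Duplicate sample columns are rejected; duplicate gene rows are
    collapsed to the row with the highest total expression (count kept
    in ``meta['duplicate_genes_dropped']``).
    """
    scale = Scale.parse(dialect)
    df = _numeric_or_report(_read_table(path), path)
    df, n_dup = _collapse_duplicate_genes(df)
    if n_dup:
        logger.info("%s: collapsed %d duplicate gene rows", path, n_dup)
    m = ExpressionMatrix(df, scale)
    m.meta["duplicate_genes_dropped"] = n_dup
    m.meta["source_path"] = str(path)
    return m


# ---------------------------------------------------------------------------
# phenotype

# TCGA sample-type strings → sample class.  Types outside this table
# (e.g. recurrent tumors) are skipped with a logged count: the analyses
# only distinguish primary / metastatic / control.
TCGA_SAMPLE_TYPE_MAP = {
    "Primary Tumor": SampleClass.PRIMARY_TUMOR,
    "Primary Blood Derived Cancer - Peripheral Blood": SampleClass.PRIMARY_TUMOR,
    "Primary Blood Derived Cancer - Bone Marrow": SampleClass.PRIMARY_TUMOR,
    "Metastatic": SampleClass.METASTATIC,
    "Additional Metastatic": SampleClass.METASTATIC,
    "Solid Tissue Normal": SampleClass.ADJACENT_NORMAL,
}


def _require_column(df: pd.DataFrame, candidates: Sequence[str], path, what: str) -> str:
    for c in candidates:
        if c in df.columns:
            return c
    raise ParseError(
        f"{path}: missing required {what} column (looked for {list(candidates)})"
    )


def load_phenotype(path, dialect: str) -> list:
    """Load a phenotype table into a list of :class:`SampleAnnotation`.

    Dialects: ``TCGA`` (columns sample, sample_type, cohort/primary
    disease), ``GTEX`` (sample, tissue/_primary_site), ``CCLE`` (DepMap
    model table).  Unrecognized TCGA sample types are skipped and
    counted in the module log.
    """
    dialect = dialect.upper()
    path = Path(path)
    if not path.exists():
        raise CartargetError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    annotations: list = []
    if dialect == "TCGA":
        s_col = _require_column(df, ["sample", "sample_id"], path, "sample")
        t_col = _require_column(df, ["sample_type", "sample type"], path, "sample_type")
        c_col = _require_column(
            df,
            ["cohort", "cancer_type", "_primary_disease", "primary_disease",
             "primary disease or tissue", "detailed_category"],
            path, "cohort",
        )
        skipped = 0
        for _, row in df.iterrows():
            cls = TCGA_SAMPLE_TYPE_MAP.get(row[t_col])
            if cls is None:
                skipped += 1
                continue
            annotations.append(
                SampleAnnotation(row[s_col], "TCGA", row[c_col], cls)
            )
        if skipped:
            logger.info("%s: skipped %d rows with unrecognized sample type", path, skipped)
    elif dialect == "GTEX":
        s_col = _require_column(df, ["sample", "sample_id"], path, "sample")
        t_col = _require_column(
            df, ["tissue", "_primary_site", "body_site", "primary_site"], path, "tissue"
        )
        for _, row in df.iterrows():
            annotations.append(
                SampleAnnotation(row[s_col], "GTEX", row[t_col], SampleClass.GTEX_NORMAL)
            )
    elif dialect == "CCLE":
        s_col = _require_column(df, ["model_id", "ModelID", "model id"], path, "model id")
        l_col = _require_column(
            df, ["lineage", "OncotreeLineage"], path, "lineage"
        )
        for _, row in df.iterrows():
            annotations.append(
                SampleAnnotation(row[s_col], "CCLE", row[l_col], SampleClass.CELL_LINE)
            )
    else:
        raise CartargetError(f"unknown phenotype dialect: {dialect!r}")
    return annotations


# ---------------------------------------------------------------------------
# cohort map & gene set


def load_cohort_map(path) -> CohortMap:
    """Two-column TSV: tumor_code <TAB> comma-separated GTEx tissues."""
    path = Path(path)
    if not path.exists():
        raise CartargetError(f"cohort map not found: {path}")
    entries = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 1 or not parts[0]:
                raise ParseError(f"{path}:{lineno}: malformed cohort map line")
            code = parts[0].strip()
            if code in entries:
                raise ParseError(f"{path}:{lineno}: duplicate tumor code {code!r}")
            tissues = []
            if len(parts) > 1 and parts[1].strip():
                tissues = [t.strip() for t in parts[1].split(",") if t.strip()]
            entries[code] = set(tissues)
    return CohortMap(entries)


def default_cohort_map() -> CohortMap:
    """The packaged tumor → GTEx tissue pairing (editable TSV).

    Transcribed from the standard TCGA/GTEx tissue correspondence; ship
    your own file via ``--map`` to revise it.
    """
    ref = resources.files("cartarget").joinpath("data/default_cohort_map.tsv")
    with resources.as_file(ref) as p:
        return load_cohort_map(p)


def load_gene_set(path, name: str | None = None) -> GeneSet:
    """One symbol per line; '#' starts a comment."""
    path = Path(path)
    if not path.exists():
        raise CartargetError(f"gene set file not found: {path}")
    symbols = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    return GeneSet(name or path.stem, set(symbols))


# ---------------------------------------------------------------------------
# gene-axis operations


def map_gene_ids(m: ExpressionMatrix, mapping: Mapping[str, str]) -> ExpressionMatrix:
    """Re-key the gene axis from ids (e.g. Ensembl) to symbols.

    Unmapped genes are dropped and counted; when two ids map to one
    symbol, the row with the highest total expression wins.
    """
    if not mapping:
        raise CartargetError("gene id mapping is empty")
    keep = [g for g in m.data.index if g in mapping]
    if not keep:
        raise CartargetError("gene id mapping covers none of the matrix genes")
    dropped = m.data.shape[0] - len(keep)
    df = m.data.loc[keep]
    df.index = pd.Index([mapping[g] for g in keep], name=m.data.index.name)
    df, n_collisions = _collapse_duplicate_genes(df)
    if dropped:
        logger.info("map_gene_ids: dropped %d unmapped genes", dropped)
    if n_collisions:
        logger.info("map_gene_ids: resolved %d symbol collisions", n_collisions)
    out = ExpressionMatrix(df, m.scale, dict(m.meta))
    out.meta["unmapped_genes_dropped"] = dropped
    out.meta["symbol_collisions_dropped"] = n_collisions
    return out


def filter_gene_set(m: ExpressionMatrix, gs: GeneSet) -> ExpressionMatrix:
    """Restrict the gene axis to a gene set, preserving input order."""
    keep = [g for g in m.data.index if g in gs.symbols]
    if not keep:
        raise CartargetError(
            f"gene set {gs.name!r} shares no genes with the matrix; "
            "a screen over it would be vacuous"
        )
    return ExpressionMatrix(m.data.loc[keep], m.scale, dict(m.meta))


# ---------------------------------------------------------------------------
# cohort assembly


def build_cohort(
    tumor_code: str,
    tcga_m: ExpressionMatrix,
    gtex_m: ExpressionMatrix,
    annotations: Iterable[SampleAnnotation],
    cmap: CohortMap,
) -> Cohort:
    """Assemble one tumor's merged matrix and sample-class sets.

    Controls pool TCGA adjacent normals with the GTEx tissues the cohort
    map assigns to this tumor.  Both matrices must be on the same scale;
    the merged matrix is converted to TPM over the shared gene axis.
    """
    if tcga_m.scale is not gtex_m.scale:
        raise CartargetError(
            f"TCGA matrix scale {tcga_m.scale.value} != GTEx scale {gtex_m.scale.value}"
        )
    tissues = cmap.tissues_for(tumor_code)

    anns = list(annotations)
    gtex_tissues_present = {a.cohort_code for a in anns if a.source_project == "GTEX"}
    missing_tissues = tissues - gtex_tissues_present
    if missing_tissues:
        raise CartargetError(
            f"cohort map tissues not present in GTEx annotation: {sorted(missing_tissues)}"
        )

    tcga_samples = set(tcga_m.sample_ids)
    gtex_samples = set(gtex_m.sample_ids)
    primary, metastatic, adjacent, gtex_ctrl = [], [], [], []
    control_tissue: dict = {}
    for a in anns:
        if a.source_project == "TCGA" and a.cohort_code == tumor_code and a.sample_id in tcga_samples:
            if a.sample_class is SampleClass.PRIMARY_TUMOR:
                primary.append(a.sample_id)
            elif a.sample_class is SampleClass.METASTATIC:
                metastatic.append(a.sample_id)
            elif a.sample_class is SampleClass.ADJACENT_NORMAL:
                adjacent.append(a.sample_id)
                control_tissue[a.sample_id] = "adjacent_normal"
        elif a.source_project == "GTEX" and a.cohort_code in tissues and a.sample_id in gtex_samples:
            gtex_ctrl.append(a.sample_id)
            control_tissue[a.sample_id] = a.cohort_code
    control = adjacent + gtex_ctrl
    if not primary:
        raise CartargetError(f"cohort {tumor_code}: no primary tumor samples")
    if not control:
        raise CartargetError(f"cohort {tumor_code}: zero control samples")

    shared_genes = [g for g in tcga_m.data.index if g in set(gtex_m.data.index)]
    if not shared_genes:
        raise CartargetError("TCGA and GTEx matrices share no genes")

    from .matrix import tpm_frame  # local import to avoid cycle at module load

    tcga_tpm = tpm_frame(tcga_m).loc[shared_genes]
    gtex_tpm = tpm_frame(gtex_m).loc[shared_genes]
    cols = primary + metastatic + adjacent
    merged = pd.concat([tcga_tpm[cols], gtex_tpm[gtex_ctrl]], axis=1)
    return Cohort(
        tumor_code=tumor_code,
        matrix=ExpressionMatrix(merged, Scale.TPM),
        primary_ids=primary,
        metastatic_ids=metastatic,
        control_ids=control,
        control_tissue=control_tissue,
    )
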
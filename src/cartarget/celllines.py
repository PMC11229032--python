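"""Cancer cell-line selection for wet-lab CAR validation.

After a candidate antigen survives the expression screens, CAR
constructs are tested in vitro against cell lines spanning a range of
target expression (high / medium / low).  This module loads DepMap/CCLE-
shaped expression and model-metadata files and filters cell lines by a
TPM threshold, optionally within one lineage.

Boundary convention: direction "above" keeps lines with expression
≥ threshold and "below" keeps expression < threshold, so the two
directions partition the (lineage-restricted) panel at any threshold.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import CartargetError, ParseError
from .io import _read_table, _numeric_or_report, _collapse_duplicate_genes
from .matrix import ExpressionMatrix, Scale, convert_scale, tpm_frame

__all__ = [
    "load_cellline_expression",
    "load_model_table",
    "select_cell_lines",
]

MODEL_COLUMNS = {
    "model_id": ["model_id", "ModelID", "model id"],
    "cell_line_name": ["cell_line_name", "CellLineName", "cell line name", "StrippedCellLineName"],
    "lineage": ["lineage", "OncotreeLineage"],
    "primary_disease": ["primary_disease", "OncotreePrimaryDisease", "primary disease"],
    "subtype": ["subtype", "OncotreeSubtype"],
    "catalog_number": ["catalog_number", "CatalogNumber", "catalog number"],
}

_SYMBOL_SUFFIX = re.compile(r"\s+\(\d+\)$")  # "CEACAM6 (4680)" -> "CEACAM6"


def load_cellline_expression(path, dialect: "str | Scale" = Scale.LOG2_TPM_PLUS_1,
                             orientation: str = "models_by_genes") -> ExpressionMatrix:
    """Load a CCLE/DepMap-shaped expression file, returned on TPM scale.

    The DepMap release ships models as rows and genes as columns (often
    "SYMBOL (entrez)") with log2(TPM+1) values; the declared dialect is
    converted back to linear TPM and the matrix is transposed to the
    gene × sample orientation the rest of the package uses.  Pass
    ``orientation="genes_by_models"`` for already-transposed files.
    """
    df = _numeric_or_report(_read_table(path), path)
    if orientation == "models_by_genes":
        df = df.T
    elif orientation != "genes_by_models":
        raise CartargetError(f"unknown orientation {orientation!r}")
    df.index = pd.Index([_SYMBOL_SUFFIX.sub("", str(g)) for g in df.index])
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate cell-line identifiers")
    df, n_dup = _collapse_duplicate_genes(df)
    m = ExpressionMatrix(df, Scale.parse(dialect))
    m = convert_scale(m, Scale.TPM)
    m.meta["duplicate_genes_dropped"] = n_dup
    m.meta["source_path"] = str(path)
    return m


def load_model_table(path) -> pd.DataFrame:
    """Load cell-line metadata, normalizing DepMap column names."""
    path = Path(path)
    if not path.exists():
        raise CartargetError(f"model table not found: {path}")
    sep = "\t"
    with open(path, "rt", encoding="utf-8") as fh:
        if "\t" not in fh.readline():
            sep = ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    renames = {}
    for canonical, candidates in MODEL_COLUMNS.items():
        found = next((c for c in candidates if c in df.columns), None)
        if found is None:
            if canonical in ("model_id", "cell_line_name", "lineage"):
                raise ParseError(f"{path}: missing required column {canonical!r}")
            df[canonical] = ""
            continue
        renames[found] = canonical
    df = df.rename(columns=renames)
    if df["model_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate model ids")
    return df[list(MODEL_COLUMNS)]


def select_cell_lines(
    gene: str,
    expression: ExpressionMatrix,
    models: pd.DataFrame,
    threshold: float,
    direction: str = "above",
    lineage: str | None = None,
) -> pd.DataFrame:
    """Cell lines whose expression of ``gene`` passes a TPM threshold.

    Returns one row per passing line (name, lineage, primary disease,
    subtype, catalog number, expression_tpm) sorted by expression
    descending, ties broken by cell-line name.
    """
    if threshold < 0:
        raise CartargetError("threshold must be >= 0")
    if direction not in ("above", "below"):
        raise CartargetError(f"direction must be 'above' or 'below', got {direction!r}")
    if gene not in expression.data.index:
        raise CartargetError(f"gene {gene!r} not present in cell-line matrix")
    tpm = tpm_frame(expression)
    values = tpm.loc[gene]

    table = models.set_index("model_id")
    known = [m for m in values.index if m in table.index]
    if not known:
        raise CartargetError("no expression columns match the model table")
    records = table.loc[known].copy()
    records["expression_tpm"] = values.loc[known].to_numpy(dtype=float)
    records["gene"] = gene

    if lineage is not None:
        if lineage not in set(models["lineage"]):
            raise CartargetError(f"unknown lineage {lineage!r}")
        records = records[records["lineage"] == lineage]

    if direction == "above":
        records = records[records["expression_tpm"] >= threshold]
    else:
        records = records[records["expression_tpm"] < threshold]
    records = records.sort_values(
        ["expression_tpm", "cell_line_name"], ascending=[False, True], kind="mergesort"
    ).reset_index()
    cols = ["gene", "model_id", "cell_line_name", "lineage", "primary_disease",
            "subtype", "catalog_number", "expression_tpm"]
    return records[cols]
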
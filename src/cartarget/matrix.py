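"""Expression-matrix container and expression-scale conversions.

All analysis in this package runs on gene × sample matrices of bulk
RNA-seq expression in TPM (transcripts per million) or a log transform
of TPM.  Three scales occur in the wild and are supported explicitly:

* ``TPM`` — linear transcripts per million, values ≥ 0.
* ``LOG2_TPM_PLUS_1`` — ``log2(TPM + 1)``, the usual display scale.
* ``XENA_LOG2_TPM_PLUS_0001`` — ``log2(TPM + 0.001)``, the encoding used
  by the UCSC Xena RSEM recompute files (values can be negative, down to
  ``log2(0.001) ≈ −9.966`` for zero expression).

The container is a thin validated wrapper around a pandas DataFrame
(genes as rows, samples as columns) carrying its scale tag, so that
every consumer knows what the numbers mean without guessing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CartargetError, ValidationError

__all__ = ["Scale", "ExpressionMatrix", "convert_scale"]

XENA_PSEUDOCOUNT = 0.001


class Scale(str, enum.Enum):
    """Supported expression scales."""

    TPM = "tpm"
    LOG2_TPM_PLUS_1 = "log2tpm1"
    XENA_LOG2_TPM_PLUS_0001 = "xena"

    @classmethod
    def parse(cls, tag: "str | Scale") -> "Scale":
        if isinstance(tag, Scale):
            return tag
        aliases = {
            "tpm": cls.TPM,
            "log": cls.LOG2_TPM_PLUS_1,
            "log2tpm1": cls.LOG2_TPM_PLUS_1,
            "log2(tpm+1)": cls.LOG2_TPM_PLUS_1,
            "xena": cls.XENA_LOG2_TPM_PLUS_0001,
            "log2(tpm+0.001)": cls.XENA_LOG2_TPM_PLUS_0001,
        }
        key = str(tag).strip().lower()
        if key not in aliases:
            raise CartargetError(f"unknown expression scale tag: {tag!r}")
        return aliases[key]


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with a declared scale.

    Parameters
    ----------
    data:
        DataFrame with unique gene identifiers as the index and unique
        sample identifiers as the columns; all values finite.
    scale:
        The :class:`Scale` the values are on.  TPM values must be ≥ 0.
    meta:
        Free-form bookkeeping (e.g. counts of genes dropped during id
        mapping) surfaced in run logs.
    """

    data: pd.DataFrame
    scale: Scale
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scale = Scale.parse(self.scale)
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("ExpressionMatrix.data must be a DataFrame")
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValidationError("expression matrix contains non-finite values")
        if self.scale is Scale.TPM and values.size and values.min() < 0:
            raise ValidationError("TPM-scale matrix contains negative values")

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def gene_values(self, gene: str) -> np.ndarray:
        if gene not in self.data.index:
            raise CartargetError(f"gene {gene!r} not present in matrix")
        return self.data.loc[gene].to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise CartargetError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(sample_ids)], self.scale, dict(self.meta))


def _to_tpm(values: np.ndarray, scale: Scale) -> np.ndarray:
    if scale is Scale.TPM:
        return values
    if scale is Scale.LOG2_TPM_PLUS_1:
        return np.maximum(np.exp2(values) - 1.0, 0.0)
    if scale is Scale.XENA_LOG2_TPM_PLUS_0001:
        return np.maximum(np.exp2(values) - XENA_PSEUDOCOUNT, 0.0)
    raise CartargetError(f"unknown scale: {scale}")


def _from_tpm(values: np.ndarray, scale: Scale) -> np.ndarray:
    if scale is Scale.TPM:
        return values
    if scale is Scale.LOG2_TPM_PLUS_1:
        return np.log2(values + 1.0)
    if scale is Scale.XENA_LOG2_TPM_PLUS_0001:
        return np.log2(values + XENA_PSEUDOCOUNT)
    raise CartargetError(f"unknown scale: {scale}")


def convert_scale(m: ExpressionMatrix, target: "str | Scale") -> ExpressionMatrix:
    """Convert an expression matrix between supported scales.

    Conversion routes through linear TPM; decoding Xena values clamps at
    zero so ``log2(0 + 0.001)`` round-trips to exactly 0 TPM.  The
    TPM → log2(TPM+1) → TPM round trip is the identity to ~1e−9 relative
    tolerance.
    """
    target = Scale.parse(target)
    if target is m.scale:
        return ExpressionMatrix(m.data.copy(), m.scale, dict(m.meta))
    tpm = _to_tpm(m.data.to_numpy(dtype=float), m.scale)
    out = _from_tpm(tpm, target)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        target,
        dict(m.meta),
    )


def tpm_frame(m: ExpressionMatrix) -> pd.DataFrame:
    """The matrix on linear TPM scale, as a DataFrame."""
    if m.scale is Scale.TPM:
        return m.data
    return convert_scale(m, Scale.TPM).data


def gene_symbol_mapping_from_frame(frame: pd.DataFrame) -> Mapping[str, str]:
    """Two-column (id, symbol) DataFrame → mapping dict."""
    if frame.shape[1] < 2:
        raise CartargetError("gene mapping table needs two columns: id, symbol")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))
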
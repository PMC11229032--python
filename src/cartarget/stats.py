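"""Shared statistical primitives.

Every screening tool reduces to the same four ingredients:

* group medians, reported both in TPM and on the log2(TPM+1) scale
  (the log-scale median is the median of the transformed values, not
  the transform of the TPM median — the two differ for skewed groups);
* fold change, the ratio of tumor to control median TPM, stabilized
  with a symmetric pseudocount so it is always finite and positive;
* log2 fold change, the *difference* of log-scale medians (again not
  log2 of the TPM ratio);
* a two-sided Mann–Whitney U test with Benjamini–Hochberg adjustment
  across whatever family of tests one call performs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .errors import CartargetError

__all__ = [
    "FC_PSEUDOCOUNT",
    "GroupSummary",
    "fold_change",
    "log2_fold_change",
    "mwu_test",
    "mwu_test_rows",
    "adjust_pvalues",
    "group_summary",
]

#: Pseudocount added to both medians in the fold-change ratio.  A
#: symmetric offset keeps FC(a,b)·FC(b,a) = 1 and makes the ratio
#: defined when a control median is exactly zero.
FC_PSEUDOCOUNT = 0.01

#: Largest group size for which the exact Mann–Whitney null distribution
#: is used (when the pooled values are tie-free).
EXACT_MWU_MAX_N = 8

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Per-group expression summary for one gene."""

    group_label: str
    n: int
    median_tpm: float
    median_log: float


def _as_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise CartargetError(f"group {name!r} is empty")
    return arr


def group_summary(label: str, tpm_values) -> GroupSummary:
    v = _as_group(tpm_values, label)
    return GroupSummary(
        group_label=label,
        n=int(v.size),
        median_tpm=float(np.median(v)),
        median_log=float(np.median(np.log2(v + 1.0))),
    )


def fold_change(tumor_values, control_values) -> float:
    """Median-of-TPM ratio, tumor over control, pseudocount-stabilized.

    ``(median(T) + ε) / (median(C) + ε)`` with ε = 0.01 TPM.
    """
    t = _as_group(tumor_values, "tumor")
    c = _as_group(control_values, "control")
    return float(
        (np.median(t) + FC_PSEUDOCOUNT) / (np.median(c) + FC_PSEUDOCOUNT)
    )


def log2_fold_change(tumor_values, control_values) -> float:
    """Difference of log2(TPM+1) medians, tumor minus control."""
    t = _as_group(tumor_values, "tumor")
    c = _as_group(control_values, "control")
    return float(
        np.median(np.log2(t + 1.0)) - np.median(np.log2(c + 1.0))
    )


def mwu_test(a, b) -> float:
    """Two-sided Mann–Whitney U p-value.

    The exact null distribution is used for tie-free samples with
    ``min(n, m) ≤ 8``; otherwise the tie-corrected normal approximation
    with continuity correction.  A degenerate pooled sample (all values
    identical) carries no rank information and returns p = 1.
    """
    x = _as_group(a, "a")
    y = _as_group(b, "b")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (min(x.size, y.size) <= EXACT_MWU_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = _sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def mwu_test_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann–Whitney p-values for two sample blocks.

    ``A`` is genes × n tumor samples, ``B`` genes × m control samples.
    Applies the same method rule as :func:`mwu_test` per row; the large-
    sample branch is vectorized across genes.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise CartargetError("row blocks must cover the same genes")
    if A.shape[1] == 0 or B.shape[1] == 0:
        raise CartargetError("a group has zero samples")
    if min(A.shape[1], B.shape[1]) <= EXACT_MWU_MAX_N:
        return np.array([mwu_test(a, b) for a, b in zip(A, B)])
    with np.errstate(invalid="ignore", divide="ignore"):
        res = _sps.mannwhitneyu(
            A, B, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
        p = np.asarray(res.pvalue, dtype=float)
    pooled = np.concatenate([A, B], axis=1)
    degenerate = np.all(pooled == pooled[:, :1], axis=1)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    return np.minimum(p, 1.0)


def adjust_pvalues(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise CartargetError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
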
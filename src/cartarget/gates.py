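"""Dual-antigen (logic-gated) CAR assessment.

A single antigen rarely combines full tumor coverage with absence from
every healthy tissue.  Logic-gated CARs combine two antigens: AND
(both required to fire), OR (either suffices), NOT (the second antigen
vetoes killing), IF-BETTER (the second antigen boosts an otherwise weak
response).  This module provides

* :func:`pair_correlation` — Pearson and Spearman correlation of two
  genes' expression, separately in tumor and control samples, on the
  log2(TPM+1) scale, plus the per-sample pairs for plotting; and
* :func:`gate_feasibility` — an explicit, threshold-based feasibility
  classifier for the four gate types.  The source workflow judges gates
  visually from the correlation plot; the quantitative rules here are a
  formalization of that judgement, with every threshold exposed in
  :class:`GateConfig` and every supporting coverage fraction returned
  alongside the verdict.

Coverage definitions (per sample group): a gene is "on" when its TPM is
≥ τ_on and "absent" when < τ_off.  Tumor coverage must reach c_min;
healthy-tissue co-coverage must stay below s_max in every tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import CartargetError, ValidationError
from .io import Cohort, SampleAnnotation
from .matrix import ExpressionMatrix, tpm_frame

__all__ = [
    "GateConfig",
    "GatePairProfile",
    "pair_correlation",
    "gate_feasibility",
    "tissue_pair_values",
]


@dataclass(frozen=True)
class GateConfig:
    """Thresholds of the gate-feasibility classifier.

    tau_on:
        TPM above which an antigen is considered present enough to
        activate a CAR (default 10 TPM).
    tau_off:
        TPM below which an antigen is considered absent (default 1 TPM);
        must be < tau_on.
    c_min:
        Minimum fraction of tumor samples the gate must cover
        (default 0.8).
    s_max:
        Maximum tolerated co-coverage fraction in any single healthy
        tissue (default 0.05); must be < c_min.
    """

    tau_on: float = 10.0
    tau_off: float = 1.0
    c_min: float = 0.8
    s_max: float = 0.05

    def __post_init__(self):
        if not self.tau_off < self.tau_on:
            raise ValidationError("tau_off must be < tau_on")
        if not (0.0 < self.c_min <= 1.0):
            raise ValidationError("c_min must be in (0, 1]")
        if not (0.0 <= self.s_max < self.c_min):
            raise ValidationError("s_max must satisfy 0 <= s_max < c_min")


@dataclass
class GatePairProfile:
    """Paired expression of two genes with per-group correlations.

    Correlations are computed on log2(TPM+1); a constant gene within a
    group makes the coefficient undefined and it is reported as NaN,
    never coerced to a number.  ``pairs`` holds per-sample TPM values
    ("sample", "group", gene_a, gene_b) for plotting.
    """

    gene_a: str
    gene_b: str
    pairs: pd.DataFrame
    tumor_pearson: float
    tumor_spearman: float
    control_pearson: float
    control_spearman: float
    gate_verdicts: dict = field(default_factory=dict)


def _corr(x: np.ndarray, y: np.ndarray) -> tuple:
    lx, ly = np.log2(x + 1.0), np.log2(y + 1.0)
    if np.all(lx == lx[0]) or np.all(ly == ly[0]):
        return float("nan"), float("nan")
    pear = float(_sps.pearsonr(lx, ly).statistic)
    spear = float(_sps.spearmanr(lx, ly).statistic)
    return pear, spear


def pair_correlation(gene_a: str, gene_b: str, cohort: Cohort) -> GatePairProfile:
    """Correlate two genes' expression in tumor and control samples."""
    for g in (gene_a, gene_b):
        if g not in cohort.matrix.data.index:
            raise CartargetError(f"gene {g!r} not present in cohort matrix")
    frames = []
    stats = {}
    for group, which in (("tumor", "primary_tumor"), ("control", "control")):
        ids = cohort.primary_ids if which == "primary_tumor" else cohort.control_ids
        if not ids:
            raise CartargetError(f"group {group!r} is empty")
        a = cohort.matrix.data.loc[gene_a, ids].to_numpy(dtype=float)
        b = cohort.matrix.data.loc[gene_b, ids].to_numpy(dtype=float)
        stats[group] = _corr(a, b)
        frames.append(pd.DataFrame({
            "sample": ids, "group": group, gene_a: a, gene_b: b,
        }))
    pairs = pd.concat(frames, ignore_index=True)
    return GatePairProfile(
        gene_a=gene_a,
        gene_b=gene_b,
        pairs=pairs,
        tumor_pearson=stats["tumor"][0],
        tumor_spearman=stats["tumor"][1],
        control_pearson=stats["control"][0],
        control_spearman=stats["control"][1],
    )


def tissue_pair_values(
    gene_a: str,
    gene_b: str,
    gtex_m: ExpressionMatrix,
    annotations,
) -> dict:
    """Per-tissue paired TPM values for two genes: tissue → (a, b) arrays."""
    for g in (gene_a, gene_b):
        if g not in gtex_m.data.index:
            raise CartargetError(f"gene {g!r} not present in GTEx matrix")
    tpm = tpm_frame(gtex_m)
    sample_set = set(gtex_m.sample_ids)
    by_tissue: dict = {}
    for a in annotations:
        if a.source_project == "GTEX" and a.sample_id in sample_set:
            by_tissue.setdefault(a.cohort_code, []).append(a.sample_id)
    return {
        tissue: (
            tpm.loc[gene_a, ids].to_numpy(dtype=float),
            tpm.loc[gene_b, ids].to_numpy(dtype=float),
        )
        for tissue, ids in sorted(by_tissue.items())
    }


def _frac(mask: np.ndarray) -> float:
    return float(np.count_nonzero(mask)) / mask.size


def gate_feasibility(
    gene_a: str,
    gene_b: str,
    cohort: Cohort,
    tissue_tables: Mapping[str, tuple],
    cfg: GateConfig | None = None,
) -> dict:
    """Classify the four dual-antigen gates for a gene pair.

    ``tissue_tables`` maps each healthy-tissue name to an (a_values,
    b_values) pair of TPM arrays (see :func:`tissue_pair_values`).
    Returns per-gate verdicts with every supporting coverage fraction:

    * AND — tumor both-on fraction ≥ c_min and, in every tissue, the
      both-on fraction ≤ s_max.
    * OR — tumor either-on fraction ≥ c_min and every tissue either-on
      fraction ≤ s_max.
    * NOT (a activating, b inhibitory) — tumor fraction(a on, b absent)
      ≥ c_min; in every tissue where a's on-fraction exceeds s_max, b
      must be present (≥ τ_off) in ≥ 1 − s_max of samples to veto.
    * IF-BETTER — AND failed only on tumor coverage, a alone covers
      ≥ c_min of tumors, and b is co-stimulatory in ≥ c_min/2 of them.
    """
    if cfg is None:
        cfg = GateConfig()
    if not tissue_tables:
        raise CartargetError("gate_feasibility needs at least one tissue table")
    for g in (gene_a, gene_b):
        if g not in cohort.matrix.data.index:
            raise CartargetError(f"gene {g!r} not present in cohort matrix")
    ta = cohort.class_values(gene_a, "primary_tumor")
    tb = cohort.class_values(gene_b, "primary_tumor")

    tumor_a_on = ta >= cfg.tau_on
    tumor_b_on = tb >= cfg.tau_on
    tumor_both = _frac(tumor_a_on & tumor_b_on)
    tumor_either = _frac(tumor_a_on | tumor_b_on)
    tumor_a_frac = _frac(tumor_a_on)
    tumor_b_frac = _frac(tumor_b_on)
    tumor_a_not_b = _frac(tumor_a_on & (tb < cfg.tau_off))

    tissue_both, tissue_either, tissue_a_on, tissue_b_present = {}, {}, {}, {}
    for tissue, (va, vb) in tissue_tables.items():
        va = np.asarray(va, dtype=float)
        vb = np.asarray(vb, dtype=float)
        if va.size == 0 or va.size != vb.size:
            raise CartargetError(f"tissue table {tissue!r} is empty or mismatched")
        a_on = va >= cfg.tau_on
        b_on = vb >= cfg.tau_on
        tissue_both[tissue] = _frac(a_on & b_on)
        tissue_either[tissue] = _frac(a_on | b_on)
        tissue_a_on[tissue] = _frac(a_on)
        tissue_b_present[tissue] = _frac(vb >= cfg.tau_off)

    max_both = max(tissue_both.values())
    max_either = max(tissue_either.values())

    and_tissue_ok = max_both <= cfg.s_max
    and_tumor_ok = tumor_both >= cfg.c_min
    and_viable = and_tumor_ok and and_tissue_ok

    or_viable = tumor_either >= cfg.c_min and max_either <= cfg.s_max

    # NOT: tissues where a alone would trigger must have the veto antigen.
    exposed = {t: f for t, f in tissue_a_on.items() if f > cfg.s_max}
    not_veto_ok = all(tissue_b_present[t] >= 1.0 - cfg.s_max for t in exposed)
    not_viable = tumor_a_not_b >= cfg.c_min and not_veto_ok

    if_better_viable = (
        and_tissue_ok
        and not and_tumor_ok
        and tumor_a_frac >= cfg.c_min
        and tumor_b_frac >= cfg.c_min / 2.0
    )

    return {
        "config": cfg,
        "AND": {
            "viable": bool(and_viable),
            "tumor_both_fraction": tumor_both,
            "max_tissue_both_fraction": max_both,
            "tissue_both_fraction": dict(tissue_both),
        },
        "OR": {
            "viable": bool(or_viable),
            "tumor_either_fraction": tumor_either,
            "max_tissue_either_fraction": max_either,
            "tissue_either_fraction": dict(tissue_either),
        },
        "NOT": {
            "viable": bool(not_viable),
            "tumor_a_on_b_absent_fraction": tumor_a_not_b,
            "exposed_tissues": sorted(exposed),
            "tissue_a_on_fraction": dict(tissue_a_on),
            "tissue_b_present_fraction": dict(tissue_b_present),
        },
        "IF_BETTER": {
            "viable": bool(if_better_viable),
            "tumor_a_fraction": tumor_a_frac,
            "tumor_b_fraction": tumor_b_frac,
            "and_failed_on_tumor_coverage_only": bool(and_tissue_ok and not and_tumor_ok),
        },
    }
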
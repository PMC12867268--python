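"""Two-group differential expression on a log2 expression matrix.

A Welch (unequal-variance) two-sample t-test per gene, BH adjustment across
genes, and the differential-expression call adj_p < 0.05 AND |log2FC| > 0.5
(strict inequalities at both thresholds). log2FC is case mean minus control
mean on the log2 scale. Input is assumed already log2-transformed; no
normalization is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, ValidationError
from .twas import bh_adjust

__all__ = ["DegResult", "diff_expr", "filter_degs"]

ADJ_P_MAX = 0.05
LFC_MIN = 0.5


@dataclass
class DegResult:
    gene_id: str
    log2fc: float
    p: float
    adj_p: float
    is_deg: bool
    direction: str  # up | down | none


def diff_expr(
    matrix: ExpressionMatrix,
    adj_p_max: float = ADJ_P_MAX,
    lfc_min: float = LFC_MIN,
) -> list[DegResult]:
    """Per-gene Welch t-test of case vs control with BH adjustment.

    Genes where both groups have zero variance and equal means get p = 1 by
    convention. Results are returned in the matrix's gene order.
    """
    cases = matrix.group_columns("case")
    controls = matrix.group_columns("control")
    if cases.shape[1] < 2 or controls.shape[1] < 2:
        raise ValidationError("each group needs >= 2 samples")
    lfc = cases.mean(axis=1) - controls.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant genes trigger a scipy precision warning; they are handled
        # explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, p = stats.ttest_ind(cases, controls, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    # zero variance in both groups: equal means -> p = 1, unequal -> p -> 0
    p[degenerate & (np.abs(lfc) < 1e-300)] = 1.0
    p[degenerate & (np.abs(lfc) >= 1e-300)] = np.nextafter(0, 1)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    adj = bh_adjust(p)
    out: list[DegResult] = []
    for gene, f, pp, ap in zip(matrix.gene_ids, lfc, p, adj):
        is_deg = bool(ap < adj_p_max and abs(f) > lfc_min)
        direction = "none" if not is_deg else ("up" if f > 0 else "down")
        out.append(DegResult(gene, float(f), float(pp), float(ap), is_deg, direction))
    return out


def filter_degs(
    results: list[DegResult],
    adj_p_max: float = ADJ_P_MAX,
    lfc_min: float = LFC_MIN,
) -> tuple[list[str], list[str]]:
    """Split flagged genes into (up, down) lists, sorted by adj_p then gene_id."""
    flagged = [
        r for r in results if r.adj_p < adj_p_max and abs(r.log2fc) > lfc_min
    ]
    flagged.sort(key=lambda r: (r.adj_p, r.gene_id))
    up = [r.gene_id for r in flagged if r.log2fc > 0]
    down = [r.gene_id for r in flagged if r.log2fc < 0]
    return up, down
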
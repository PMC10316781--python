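"""Tissue-specificity flags, module-membership flags and specificity matrices.

A gene is tissue-specific when its (residualized) expression in a tissue
is at least ``fold`` (default 5) times its mean across *all* tissues —
including the focal one, which makes the rule unsatisfiable below 6
tissues, hence the guard.  Module-membership (MM) specificity instead
compares against the mean of the *other* tissues (default fold 3.5), with
negative MM values floored at 0 since a fold change over a negative
baseline is undefined.

The specificity matrix divides each gene's mean cell-type expression by
its row total, giving the fraction of the gene's expression attributable
to each cell type (rows sum to 1); the same ratio for a single
(gene, cell type) pair is exposed as the gene-contribution report.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


def tissue_specific_flags(expr: pd.DataFrame, fold: float = 5.0) -> pd.DataFrame:
    """Boolean gene × tissue flags: value >= fold × mean over all tissues.

    Requires at least 6 tissues: with T <= fold tissues, a value of
    ``fold × mean`` would have to exceed the row total, so the rule could
    never fire and silence would be misleading.
    """
    if expr.shape[1] < 6:
        raise ConfigurationError(
            f"tissue-specificity rule needs >= 6 tissues, got {expr.shape[1]}; "
            f"with T <= fold the threshold fold*mean exceeds any single value"
        )
    row_mean = expr.mean(axis=1)
    return expr.ge(fold * row_mean, axis=0)


def mm_specific_flags(mm: pd.DataFrame, fold: float = 3.5,
                      baseline: str = "mean") -> pd.DataFrame:
    """Boolean gene × tissue flags for module-membership specificity.

    flag(g, t) ⇔ mm(g, t) > 0 and mm(g, t) >= fold × baseline over the
    *other* tissues, where negative values are floored at 0 before taking
    the baseline.  ``baseline`` is ``"mean"`` (default) or ``"max"``.
    """
    if mm.shape[1] < 2:
        raise ConfigurationError("module-membership flags need >= 2 tissues")
    if baseline not in ("mean", "max"):
        raise ValueError(f"baseline must be 'mean' or 'max', got {baseline!r}")
    vals = mm.to_numpy(dtype=float)
    floored = np.maximum(vals, 0.0)
    T = vals.shape[1]
    totals = floored.sum(axis=1, keepdims=True)
    if baseline == "mean":
        base = (totals - floored) / (T - 1)
    else:
        # max over others: recompute per column from the two row-wise maxima
        order = np.sort(floored, axis=1)
        top, second = order[:, -1:], order[:, -2:-1]
        base = np.where(floored == top, second, top)
    flags = (vals > 0) & (vals >= fold * base)
    return pd.DataFrame(flags, index=mm.index, columns=mm.columns)


def specificity_matrix(celltype_means: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize mean cell-type expression into a specificity matrix.

    Rows sum to 1; genes with all-zero expression are dropped and logged.
    Negative inputs are rejected.
    """
    if (celltype_means.to_numpy() < 0).any():
        raise ValueError("cell-type mean expression must be non-negative")
    totals = celltype_means.sum(axis=1)
    zero = totals == 0
    if zero.any():
        log.warning("dropping %d genes with all-zero expression: %s",
                    int(zero.sum()), list(celltype_means.index[zero][:5]))
    kept = celltype_means.loc[~zero]
    return kept.div(kept.sum(axis=1), axis=0)


def gene_contribution(gene: str, cell_type: str,
                      celltype_means: pd.DataFrame) -> float:
    """Mean expression of the gene in the cell type over its total expression.

    Returns NaN (with a log entry) when the gene's total expression is 0.
    """
    row = celltype_means.loc[gene]
    total = row.sum()
    if total == 0:
        log.warning("gene %s has zero total expression; contribution undefined", gene)
        return float("nan")
    return float(row[cell_type] / total)
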
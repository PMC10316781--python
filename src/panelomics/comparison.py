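"""Pairwise statistical comparison of features across the four gene panels.

Numeric features are compared with the Wilcoxon rank-sum (Mann-Whitney U)
test, categorical features with chi-squared tests; each feature is tested
over all six pairs of panels (adult, childhood, overlap, control) and the
six p-values are Benjamini-Hochberg adjusted as one family.

The Wilcoxon test uses exact enumeration for small samples (n+m <= 12;
scipy's exact method when tie-free, in-package permutation enumeration
when tied) and the tie-corrected normal approximation with continuity
correction otherwise.  2×2 chi-squared tests apply the Yates continuity
correction by default, with the deviation |O−E|−0.5 floored at 0.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

PANELS = ("adult", "childhood", "overlap", "control")
EXACT_LIMIT = 12


def _exact_permutation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumerating group assignments.

    Handles ties (pairs scoring 0.5); for identical multisets the observed
    U sits at the null center and p = 1.
    """
    from itertools import combinations as comb

    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = float((x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum())
    center = n * m / 2.0
    dev_obs = abs(u_obs - center)
    hits = total = 0
    idx = np.arange(n + m)
    for chosen in comb(range(n + m), n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(chosen)] = True
        xs, ys = pooled[mask], pooled[~mask]
        u = float((xs[:, None] > ys[None, :]).sum() + 0.5 * (xs[:, None] == ys[None, :]).sum())
        total += 1
        if abs(u - center) >= dev_obs - 1e-12:
            hits += 1
    del idx
    return u_obs, hits / total


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U of x) with a two-sided p-value.

    Exact for n+m <= 12 (enumeration), tie-corrected normal approximation
    with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    small = x.size + y.size <= EXACT_LIMIT
    tied = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if small and not tied:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if small and tied:
        return _exact_permutation(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def chisq_2x2(table, continuity: bool = True) -> tuple[float, float]:
    """Chi-squared test of a 2×2 table with optional Yates correction.

    Statistic = Σ max(|O−E|−0.5, 0)² / E with continuity (plain Pearson
    otherwise); p from the chi-squared distribution with 1 df.  A zero
    margin is degenerate: p = 1 with a warning.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 0.0, 1.0
    expected = np.outer(rows, cols) / obs.sum()
    dev = np.abs(obs - expected)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def chisq_contingency(table: np.ndarray, continuity: bool = True) -> tuple[float, float]:
    """Chi-squared for an R×C contingency table (Yates only when 2×2)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape == (2, 2):
        return chisq_2x2(obs, continuity=continuity)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
        if obs.shape[0] < 2 or obs.shape[1] < 2:
            warnings.warn("degenerate contingency table; p = 1", stacklevel=2)
            return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvals, pd.Series):
        return pd.Series(adj, index=pvals.index)
    return adj


def compare_feature(
    table: pd.DataFrame,
    feature: str,
    dtype: str | None = None,
    panel_column: str = "panel",
    continuity: bool = True,
) -> pd.DataFrame:
    """Compare one feature across all six panel pairs.

    Numeric features get Wilcoxon rank-sum tests with per-group medians;
    categorical features get chi-squared tests on the pair's contingency
    table with per-group category proportions.  The six p-values are
    BH-adjusted as one family; a pair with a group below 2 observations is
    skipped with a logged reason.
    """
    if feature not in table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    if dtype is None:
        dtype = "numeric" if pd.api.types.is_numeric_dtype(table[feature]) else "categorical"
    groups = {p: table.loc[table[panel_column] == p, feature].dropna()
              for p in PANELS}
    rows = []
    for g1, g2 in combinations(PANELS, 2):
        a, b = groups[g1], groups[g2]
        if len(a) < 2 or len(b) < 2:
            log.info("skipping %s %s-vs-%s: group below 2 observations", feature, g1, g2)
            continue
        if dtype == "numeric":
            stat, p = wilcoxon_rank_sum(a.to_numpy(), b.to_numpy())
            s1, s2 = float(a.median()), float(b.median())
            test = "wilcoxon"
        else:
            ct = pd.crosstab(
                pd.concat([a, b]),
                pd.Series(["g1"] * len(a) + ["g2"] * len(b), index=list(a.index) + list(b.index)),
            )
            stat, p = chisq_contingency(ct.to_numpy(), continuity=continuity)
            s1 = str((a.value_counts(normalize=True).round(4)).to_dict())
            s2 = str((b.value_counts(normalize=True).round(4)).to_dict())
            test = "chisq"
        rows.append({
            "feature": feature, "group1": g1, "group2": g2, "test": test,
            "statistic": stat, "p": p, "n1": len(a), "n2": len(b),
            "summary1": s1, "summary2": s2,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = fdr_bh(out["p"].to_numpy())
    return out


def compare_all_features(
    table: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    panel_column: str = "panel",
) -> pd.DataFrame:
    """Run :func:`compare_feature` for every feature column in the table."""
    dtypes = {}
    if metadata is not None:
        dtypes = metadata.set_index("feature")["dtype"].to_dict()
    frames = []
    for col in table.columns:
        if col == panel_column:
            continue
        frames.append(compare_feature(table, col, dtype=dtypes.get(col),
                                      panel_column=panel_column))
    return pd.concat([f for f in frames if not f.empty], ignore_index=True)
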
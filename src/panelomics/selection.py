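"""Redundancy pruning, class-balanced recursive feature elimination, embedding.

The selection protocol mirrors the unsupervised analysis of the full
feature set: features with pairwise Pearson |r| above 0.9 are greedily
pruned; then, over many repeats, a random half of the disease genes is
matched with an equal-size bootstrap sample of control genes and
recursive feature elimination (RFE) with a logistic-link linear model is
run, scoring candidate subset sizes by cross-validated Cohen's κ.  A
feature's selection frequency is the fraction of repeats in which it
appears in the best subset; features at frequency >= 0.8 are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from panelomics._rng import substream

log = logging.getLogger(__name__)


@dataclass
class RFEConfig:
    corr_threshold: float = 0.9
    repeats: int = 50
    disease_fraction: float = 0.5
    keep_frequency: float = 0.8
    cv_folds: int = 5
    size_rule: str = "one_se"       # or "best": maximize CV kappa outright
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("corr_threshold", "disease_fraction", "keep_frequency"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.repeats < 2:
            raise ValueError("repeats must be >= 2")
        if self.size_rule not in ("one_se", "best"):
            raise ValueError(f"size_rule must be 'one_se' or 'best', got {self.size_rule!r}")


@dataclass
class SelectionReport:
    frequencies: pd.Series
    retained: list[str]
    per_repeat: list[list[str]]
    pruned_by_correlation: list[str] = field(default_factory=list)


def prune_correlated(features: pd.DataFrame, threshold: float = 0.9
                     ) -> tuple[list[str], list[str]]:
    """Greedy removal of features with pairwise Pearson |r| above threshold.

    Constant columns are removed first (their correlation is undefined).
    While any pair exceeds the threshold, the member with the larger mean
    absolute correlation to all remaining features is dropped; ties break
    deterministically by feature name (the lexicographically later one
    goes).  Returns (retained, pruned).
    """
    pruned: list[str] = []
    const = [c for c in features.columns if features[c].nunique() <= 1]
    pruned.extend(const)
    work = features.drop(columns=const)
    corr = work.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    while not corr.empty and corr.values.max() > threshold:
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        ma, mb = corr[a].mean(), corr[b].mean()
        if ma > mb:
            drop = a
        elif mb > ma:
            drop = b
        else:
            drop = max(a, b)
        pruned.append(drop)
        corr = corr.drop(index=drop, columns=drop)
    return list(corr.columns), pruned


def cohen_kappa(predicted, truth) -> float:
    """Cohen's κ = (p_o − p_e)/(1 − p_e); κ = 1 when p_e = 1 and agreement holds."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    n = len(truth)
    labels = np.union1d(predicted, truth)
    p_o = float((predicted == truth).mean())
    p_e = sum(
        (predicted == lab).mean() * (truth == lab).mean() for lab in labels
    )
    if p_e >= 1.0 - 1e-12:
        return 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    return (p_o - p_e) / (1 - p_e)


def _size_grid(n_features: int) -> list[int]:
    """Candidate subset sizes: the full set plus powers of two below it."""
    sizes = [n_features]
    k = 1
    while 2 ** k < n_features:
        k += 1
    for e in range(k - 1, -1, -1):
        sizes.append(2 ** e)
    return sizes


def _cv_kappa_folds(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    kappas = []
    for train, test in skf.split(X, y):
        model = LogisticRegression(max_iter=200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X[train], y[train])
        kappas.append(cohen_kappa(model.predict(X[test]), y[test]))
    return np.asarray(kappas)


def _rfe_once(X: pd.DataFrame, y: np.ndarray, folds: int, seed: int,
              size_rule: str = "one_se") -> list[str]:
    """One RFE pass: rank by |standardized coefficient| and shrink through
    the size grid, scoring each candidate size by cross-validated κ.

    ``size_rule="one_se"`` takes the smallest size whose mean κ is within
    one standard error of the maximum (the 1-SE parsimony rule);
    ``"best"`` takes the κ-maximizing size, ties to the smaller size.
    """
    cols = list(X.columns)
    Xz = (X - X.mean()) / X.std(ddof=0).replace(0, 1.0)
    results: list[tuple[float, float, int, list[str]]] = []
    current = cols
    for size in _size_grid(len(cols)):
        if size < len(current):
            model = LogisticRegression(max_iter=200)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(Xz[current].to_numpy(), y)
            rank = np.abs(model.coef_[0])
            order = np.argsort(-rank, kind="stable")
            current = [current[i] for i in order[:size]]
        ks = _cv_kappa_folds(Xz[current].to_numpy(), y, folds, seed)
        se = float(ks.std(ddof=1) / np.sqrt(len(ks))) if len(ks) > 1 else 0.0
        results.append((float(ks.mean()), se, size, list(current)))
    if size_rule == "best":
        best = max(results, key=lambda t: (t[0], -t[2]))
        return best[3]
    best_mean, best_se, _, _ = max(results, key=lambda t: t[0])
    within = [t for t in results if t[0] >= best_mean - best_se]
    return min(within, key=lambda t: t[2])[3]


def balanced_rfe(features: pd.DataFrame, labels: pd.Series,
                 config: RFEConfig) -> SelectionReport:
    """Class-balanced RFE with selection-frequency aggregation.

    ``labels`` maps each gene to ``disease`` or ``control``.  Per repeat:
    a without-replacement sample of ``disease_fraction`` of the disease
    genes is paired with an equal-size bootstrap (with replacement)
    sample of controls, and one RFE pass records its best subset.
    Frequencies are fractions of repeats; retained features are those at
    or above ``keep_frequency``.
    """
    labels = labels.loc[features.index]
    disease = features.index[labels == "disease"]
    control = features.index[labels == "control"]
    if len(disease) == 0 or len(control) == 0:
        raise ValueError("both disease and control genes are required")
    if features.drop_duplicates().shape[0] <= 1:
        log.warning("degenerate feature matrix: all rows identical")

    hits = pd.Series(0.0, index=features.columns)
    per_repeat: list[list[str]] = []
    n_pick = max(2, int(round(config.disease_fraction * len(disease))))
    for r in range(config.repeats):
        rng = substream(config.seed, "selection", r)
        d_idx = rng.choice(len(disease), size=min(n_pick, len(disease)), replace=False)
        c_idx = rng.choice(len(control), size=len(d_idx), replace=True)
        rows = list(disease[d_idx]) + list(control[c_idx])
        X = features.loc[rows].reset_index(drop=True)
        y = np.array([1] * len(d_idx) + [0] * len(c_idx))
        selected = _rfe_once(X, y, config.cv_folds, seed=int(rng.integers(2 ** 31)),
                             size_rule=config.size_rule)
        per_repeat.append(selected)
        hits[selected] += 1
    freqs = hits / config.repeats
    retained = list(freqs.index[freqs >= config.keep_frequency])
    return SelectionReport(freqs, retained, per_repeat)


def embed_2d(features: pd.DataFrame, seed: int = 0,
             n_neighbors: int = 15, min_dist: float = 0.1) -> pd.DataFrame:
    """2-D UMAP embedding of z-scored features (deterministic given seed).

    The neighbor count is shrunk (with a warning) when there are fewer
    genes than neighbors requested.
    """
    if len(features) < 3:
        raise ValueError("embedding needs >= 3 genes")
    import umap  # deferred: slow import

    nn = n_neighbors
    if nn >= len(features):
        nn = max(2, len(features) - 1)
        log.warning("n_neighbors %d >= n genes %d; shrunk to %d",
                    n_neighbors, len(features), nn)
    Xz = (features - features.mean()) / features.std(ddof=0).replace(0, 1.0)
    reducer = umap.UMAP(n_components=2, n_neighbors=nn, min_dist=min_dist,
                        random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(Xz.to_numpy())
    return pd.DataFrame(coords, index=features.index, columns=["umap1", "umap2"])
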
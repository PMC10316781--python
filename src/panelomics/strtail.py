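"""Screenable STR locus selection and the case/control top-1% comparison.

The screen considers naturally-occurring tri- to hexanucleotide STRs in
coding exons or 5'UTRs of panel genes (known-pathogenic expansion loci
are tagged but kept).  At each locus, every individual contributes its
maximum allele repeat count; per group the mean of the largest
``ceil(q*n)`` values (default q = 0.01) is compared between cases and
controls, reported as the signed difference (case − control).

No hypothesis test is attached by default — the per-locus tail
difference is descriptive — but a label-permutation test is available
for synthetic validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from panelomics._rng import stream
from panelomics.annotation import STRLocus

log = logging.getLogger(__name__)

SCREEN_PERIODS = frozenset({3, 4, 5, 6})
SCREEN_CONTEXTS = frozenset({"coding_exon", "five_prime_utr"})


@dataclass
class TailConfig:
    quantile: float = 0.01
    min_individuals_per_group: int = 100
    known_pathogenic_loci: tuple = ()
    pooled: bool = False            # pool maxima across loci instead of per-locus

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 0.5:
            raise ValueError("quantile must lie in (0, 0.5)")


@dataclass
class TailComparisonResult:
    locus_id: str
    case_group: str
    n_case: int
    n_control: int
    case_tail_mean: float
    control_tail_mean: float
    difference: float               # case − control
    case_quartiles: tuple = ()
    control_quartiles: tuple = ()
    skipped_reason: str | None = None


def select_screen_loci(
    catalog: list[STRLocus],
    panel_genes: set[str] | list[str],
    periods: frozenset = SCREEN_PERIODS,
    contexts: frozenset = SCREEN_CONTEXTS,
    known_pathogenic: tuple = (),
) -> pd.DataFrame:
    """Restrict a context-annotated catalog to screenable loci.

    Returns a frame (locus_id, gene_ids, period, context, known_pathogenic)
    of loci in panel genes with allowed period and context.  Loci in
    ``known_pathogenic`` are tagged, not removed.
    """
    panel_genes = set(panel_genes)
    known = set(known_pathogenic)
    rows = []
    for locus in catalog:
        if locus.context is None:
            raise ValueError(f"locus {locus.locus_id} lacks a context annotation")
        if locus.period not in periods or locus.context not in contexts:
            continue
        genes_hit = panel_genes.intersection(locus.gene_ids)
        if not genes_hit:
            continue
        rows.append({
            "locus_id": locus.locus_id,
            "gene_ids": ",".join(sorted(genes_hit)),
            "period": locus.period,
            "context": locus.context,
            "known_pathogenic": locus.locus_id in known,
        })
    return pd.DataFrame(rows, columns=["locus_id", "gene_ids", "period",
                                       "context", "known_pathogenic"])


def max_allele(allele1, allele2=None) -> float:
    """Maximum of the available alleles; NaN when both are missing."""
    vals = [v for v in (allele1, allele2) if v is not None and not pd.isna(v)]
    if not vals:
        return float("nan")
    return float(max(vals))


def _max_alleles(genotypes: pd.DataFrame) -> pd.Series:
    """Per-row maximum allele; rows with no allele dropped (logged)."""
    mx = genotypes[["allele1", "allele2"]].max(axis=1, skipna=True)
    missing = mx.isna()
    if missing.any():
        log.info("excluding %d genotypes with no alleles", int(missing.sum()))
    return mx[~missing]


def _tail_values(values: pd.Series, ids: pd.Series, q: float) -> np.ndarray:
    """The ceil(q*n) largest values; boundary ties resolved by individual id."""
    k = math.ceil(q * len(values))
    order = pd.DataFrame({"value": values.to_numpy(), "id": ids.to_numpy()})
    order = order.sort_values(["value", "id"], ascending=[False, True], kind="stable")
    return order["value"].to_numpy()[:k]


def top_tail_compare(
    locus_id: str,
    genotypes: pd.DataFrame,
    case_group: str,
    config: TailConfig,
) -> TailComparisonResult:
    """Compare the top-``q`` maximum-allele tails of one case group vs controls.

    ``genotypes`` columns: individual_id, cohort, locus_id, allele1,
    allele2.  Individuals missing a genotype at the locus are excluded at
    that locus only.  A group below ``min_individuals_per_group`` skips
    the locus with a reason.
    """
    at_locus = genotypes[genotypes["locus_id"] == locus_id]
    mx = _max_alleles(at_locus)
    kept = at_locus.loc[mx.index]
    case = kept[kept["cohort"] == case_group]
    control = kept[kept["cohort"] == "control"]
    n_case, n_control = len(case), len(control)
    if min(n_case, n_control) < config.min_individuals_per_group:
        return TailComparisonResult(
            locus_id, case_group, n_case, n_control,
            float("nan"), float("nan"), float("nan"),
            skipped_reason=f"group below {config.min_individuals_per_group} individuals",
        )
    case_tail = _tail_values(mx[case.index], case["individual_id"], config.quantile)
    ctrl_tail = _tail_values(mx[control.index], control["individual_id"], config.quantile)
    cm, km = float(case_tail.mean()), float(ctrl_tail.mean())
    quart = lambda s: tuple(np.percentile(s, [25, 50, 75]))
    return TailComparisonResult(
        locus_id, case_group, n_case, n_control, cm, km, cm - km,
        case_quartiles=quart(mx[case.index]), control_quartiles=quart(mx[control.index]),
    )


def aggregate_tails(
    locus_panel: pd.DataFrame,
    genotypes: pd.DataFrame,
    case_groups: tuple = ("case_adult", "case_childhood"),
    config: TailConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus tail comparisons plus pooled summaries by locus class.

    Returns ``(per_locus, pooled)``: one row per locus × case group, and
    pooled mean differences split by {known pathogenic, naturally
    occurring} loci and case group.  With ``config.pooled`` the maxima of
    all loci in a class are pooled before taking the tail, instead of
    averaging per-locus differences.
    """
    if locus_panel.empty:
        log.warning("empty locus panel: no loci passed selection")
        return (pd.DataFrame(), pd.DataFrame())
    config = config or TailConfig()
    by_locus = dict(tuple(genotypes.groupby("locus_id", sort=False)))
    empty = genotypes.iloc[0:0]
    rows = []
    for rec in locus_panel.itertuples():
        at_locus = by_locus.get(rec.locus_id, empty)
        for group in case_groups:
            r = top_tail_compare(rec.locus_id, at_locus, group, config)
            rows.append({
                "locus_id": r.locus_id, "case_group": r.case_group,
                "known_pathogenic": bool(rec.known_pathogenic),
                "n_case": r.n_case, "n_control": r.n_control,
                "case_tail_mean": r.case_tail_mean,
                "control_tail_mean": r.control_tail_mean,
                "difference": r.difference,
                "skipped_reason": r.skipped_reason,
            })
    per_locus = pd.DataFrame(rows)

    pooled_rows = []
    valid = per_locus[per_locus["skipped_reason"].isna()]
    for known in (True, False):
        for group in case_groups:
            cls = "known_expansion" if known else "naturally_occurring"
            sub = valid[(valid["known_pathogenic"] == known)
                        & (valid["case_group"] == group)]
            if sub.empty:
                continue
            if config.pooled:
                loci = sub["locus_id"]
                gt = genotypes[genotypes["locus_id"].isin(loci)]
                mx = _max_alleles(gt)
                kept = gt.loc[mx.index]
                diff = float("nan")
                case = kept[kept["cohort"] == group]
                ctrl = kept[kept["cohort"] == "control"]
                if len(case) and len(ctrl):
                    ct = _tail_values(mx[case.index], case["individual_id"], config.quantile)
                    kt = _tail_values(mx[ctrl.index], ctrl["individual_id"], config.quantile)
                    diff = float(ct.mean() - kt.mean())
            else:
                diff = float(sub["difference"].mean())
            pooled_rows.append({
                "locus_class": cls, "case_group": group,
                "n_loci": len(sub), "mean_difference": diff,
            })
    return per_locus, pd.DataFrame(pooled_rows)


def permutation_test(
    locus_id: str,
    genotypes: pd.DataFrame,
    case_group: str,
    config: TailConfig,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Label-permutation p for a positive tail difference at one locus."""
    obs = top_tail_compare(locus_id, genotypes, case_group, config).difference
    if np.isnan(obs):
        return float("nan")
    at_locus = genotypes[genotypes["locus_id"] == locus_id]
    mx = _max_alleles(at_locus)
    kept = at_locus.loc[mx.index]
    mask = kept["cohort"].isin([case_group, "control"])
    vals = mx[kept[mask].index].to_numpy()
    n_case = int((kept.loc[mask, "cohort"] == case_group).sum())
    rng = stream(seed, "misc")
    q = config.quantile
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(vals))
        cv, kv = vals[perm[:n_case]], vals[perm[n_case:]]
        kc = math.ceil(q * len(cv))
        kk = math.ceil(q * len(kv))
        diff = np.sort(cv)[-kc:].mean() - np.sort(kv)[-kk:].mean()
        hits += diff >= obs
    return (1 + hits) / (n_perm + 1)
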
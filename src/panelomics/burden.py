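"""Gene-based case/control rare-variant burden testing.

Qualifying variants are rare (MAF < 0.1% under a dominant model, < 1%
under a recessive model) and satisfy one of four scenario predicates:
predicted LoF; predicted pathogenic (score > 0.8); predicted pathogenic
within a constrained coding region; or de novo (restricted to probands
where de novo calling was possible).  A proband carries a gene when it
has >= 1 passing dominant variant or >= 2 passing recessive alleles
(homozygous counts as two) in that gene.

Each test contrasts carriers in one case group against controls with a
one-sided Fisher's exact test (upper hypergeometric tail); tests with
fewer than ``min_probands`` total carriers are dropped before a single
Benjamini-Hochberg correction across all retained tests of all
scenarios.  The default test design crosses panels against the opposite
onset group: childhood genes × adult cases, adult genes × childhood
cases, and overlap genes × both case groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from panelomics.comparison import fdr_bh

log = logging.getLogger(__name__)

MAF_THRESHOLDS = {"dominant": 0.001, "recessive": 0.01}

SCENARIOS = {
    "lof": lambda df: df["lof"].astype(bool),
    "pathogenic": lambda df: df["score"] > 0.8,
    "pathogenic_ccr": lambda df: (df["score"] > 0.8) & df["ccr"].astype(bool),
    "de_novo": lambda df: df["de_novo"].astype(bool) & df["de_novo_evaluable"].astype(bool),
}

#: (panel class, case group) combinations tested against controls
DEFAULT_DESIGN = (
    ("childhood", "case_adult"),
    ("adult", "case_childhood"),
    ("overlap", "case_adult"),
    ("overlap", "case_childhood"),
)


@dataclass
class BurdenConfig:
    scenarios: tuple = tuple(SCENARIOS)
    design: tuple = DEFAULT_DESIGN
    min_probands: int = 4
    maf_thresholds: dict | None = None
    haldane_correction: bool = True


def qualify_carriers(variants: pd.DataFrame, scenario: str,
                     maf_thresholds: dict | None = None) -> pd.DataFrame:
    """Per-gene carrier probands under a scenario's filters.

    Returns a frame with columns gene_id, proband_id (one row per
    carrier).  Variants with missing MAF are excluded and logged.
    """
    if scenario not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario!r}; known: {tuple(SCENARIOS)}")
    thresholds = maf_thresholds or MAF_THRESHOLDS
    df = variants.copy()
    missing = df["maf"].isna()
    if missing.any():
        log.info("excluding %d variants with missing MAF", int(missing.sum()))
        df = df[~missing]
    limit = df["moi"].map(thresholds)
    df = df[df["maf"] < limit]
    df = df[SCENARIOS[scenario](df)]
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "proband_id"])

    dom = df[df["moi"] == "dominant"]
    carriers = dom[["gene_id", "proband_id"]].drop_duplicates()

    rec = df[df["moi"] == "recessive"].copy()
    if not rec.empty:
        rec["alleles"] = np.where(rec["genotype"] == "hom", 2, 1)
        dose = rec.groupby(["gene_id", "proband_id"])["alleles"].sum()
        biallelic = dose[dose >= 2].reset_index()[["gene_id", "proband_id"]]
        carriers = pd.concat([carriers, biallelic]).drop_duplicates()
    return carriers.reset_index(drop=True)


def fisher_one_sided(a: int, b: int, c: int, d: int,
                     haldane: bool = True) -> tuple[float, float]:
    """One-sided (enrichment) Fisher's exact test on ((a, b), (c, d)).

    ``a``/``b`` are case carriers/non-carriers, ``c``/``d`` controls.  The
    p-value is the upper hypergeometric tail P(X >= a) given the margins;
    the odds ratio is the sample cross-product (a·d)/(b·c) with the
    Haldane-Anscombe 0.5 correction applied to all cells when any is 0.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    n = a + b + c + d
    p = float(stats.hypergeom.sf(a - 1, n, a + b, a + c)) if n > 0 else 1.0
    p = min(p, 1.0)
    if 0 in (a, b, c, d) and haldane:
        a2, b2, c2, d2 = (v + 0.5 for v in (a, b, c, d))
    else:
        a2, b2, c2, d2 = a, b, c, d
    odds = (a2 * d2) / (b2 * c2) if b2 * c2 > 0 else float("inf")
    return odds, p


def run_burden(
    variants: pd.DataFrame,
    panels: pd.DataFrame,
    cohorts: pd.DataFrame,
    config: BurdenConfig | None = None,
) -> pd.DataFrame:
    """Burden tests over the panel × case-group design, with global FDR.

    ``panels``: columns gene_id, panel; ``cohorts``: columns
    individual_id, cohort (case_adult / case_childhood / control).
    Tests with fewer than ``min_probands`` total carriers are dropped
    before BH correction across every retained test of every scenario.
    """
    config = config or BurdenConfig()
    cohort_of = cohorts.set_index("individual_id")["cohort"]
    n_by_group = cohort_of.value_counts()
    n_controls = int(n_by_group.get("control", 0))

    rows = []
    for scenario in config.scenarios:
        carriers = qualify_carriers(variants, scenario, config.maf_thresholds)
        if not carriers.empty:
            carriers = carriers.assign(cohort=carriers["proband_id"].map(cohort_of))
        for panel_class, case_group in config.design:
            n_cases = int(n_by_group.get(case_group, 0))
            if n_cases == 0:
                raise ValueError(f"empty case group {case_group!r}")
            genes = panels.loc[panels["panel"] == panel_class, "gene_id"]
            for gene in genes:
                sub = carriers[carriers["gene_id"] == gene] if not carriers.empty else carriers
                a = int((sub["cohort"] == case_group).sum()) if not sub.empty else 0
                c = int((sub["cohort"] == "control").sum()) if not sub.empty else 0
                if a + c < config.min_probands:
                    continue
                b, d = n_cases - a, n_controls - c
                odds, p = fisher_one_sided(a, b, c, d, haldane=config.haldane_correction)
                rows.append({
                    "gene_id": gene, "panel": panel_class, "case_group": case_group,
                    "scenario": scenario, "case_carriers": a, "case_noncarriers": b,
                    "control_carriers": c, "control_noncarriers": d,
                    "odds_ratio": odds, "p": p,
                })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = fdr_bh(out["p"].to_numpy())
    out["n_tests_in_family"] = len(out)
    out["log2_or"] = np.log2(out["odds_ratio"])
    out["neg_log10_p_adj"] = -np.log10(out["p_adj"])
    return out
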
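"""Planted-effect recovery and null-calibration experiments.

Each function runs a self-contained simulation experiment at a reduced
but statistically adequate scale: generate data with a known planted
effect (or none), run the corresponding pipeline stage, and summarize
recovery or calibration.  These experiments back both the validation
test suite and the reproduction script; the problem sizes are chosen so
each experiment completes in minutes on one CPU.

All randomness descends from the single ``seed`` argument via the
package's stream-splitting scheme, so results are reproducible and
experiments are independent of each other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from panelomics import burden, comparison, ewce, expression, selection, simulate, strtail
from panelomics._rng import substream


# ---------------------------------------------------------------------------
# worked example: repeat-expansion mechanism proportions
# ---------------------------------------------------------------------------

#: Repeat-expansion mechanism counts by onset panel: 34.8% of the 23
#: adult-onset genes (8) versus 0.5% of the 213 childhood-onset genes (1).
REPEAT_MECHANISM_TABLE = ((8, 23 - 8), (1, 213 - 1))


def repeat_mechanism_chisq() -> tuple[float, float]:
    """Yates-corrected chi-squared on the repeat-expansion mechanism table."""
    return comparison.chisq_2x2(REPEAT_MECHANISM_TABLE, continuity=True)


# ---------------------------------------------------------------------------
# burden: odds-ratio recovery and null FDR calibration
# ---------------------------------------------------------------------------

def burden_or_recovery(seed: int, n_cohorts: int = 500,
                       n_cases: int = 816, n_controls: int = 6658,
                       case_carriers: int = 6, control_carriers: int = 7) -> dict:
    """Recovery of a planted odds ratio over simulated cohorts.

    Plants carrier rates ``case_carriers/n_cases`` vs
    ``control_carriers/n_controls`` (defaults give a true cross-product OR
    of 7.038), simulates ``n_cohorts`` cohorts and reports the
    log-scale (geometric) mean of the per-cohort sample ORs — the
    conventional way odds ratios are averaged — plus the fraction of
    cohorts significant by one-sided Fisher at 0.05.
    """
    true_or = (case_carriers * (n_controls - control_carriers)) / (
        (n_cases - case_carriers) * control_carriers)
    log_ors, sig = [], 0
    for i in range(n_cohorts):
        rep_seed = int(substream(seed, "misc", i).integers(2 ** 31))
        cfg = simulate.SimConfig(seed=rep_seed, n_genes=10, n_cases=n_cases,
                                 n_controls=n_controls, case_adult_fraction=1.0)
        variants = simulate.gen_variants(
            cfg, {"G00001": (case_carriers / n_cases, control_carriers / n_controls)})
        a = int((variants["cohort"] != "control").sum())
        c = int((variants["cohort"] == "control").sum())
        odds, p = burden.fisher_one_sided(a, n_cases - a, c, n_controls - c)
        log_ors.append(np.log(odds))
        sig += p < 0.05
    return {
        "true_or": true_or,
        "geometric_mean_or": float(np.exp(np.mean(log_ors))),
        "fraction_significant": sig / n_cohorts,
        "n_cohorts": n_cohorts,
    }


def burden_null_fdr(seed: int, n_genes: int = 100,
                    n_cases: int = 816, n_controls: int = 6658,
                    rate: float = 10 / 6658) -> dict:
    """Fraction of genes reaching FDR significance when rates are equal."""
    cfg = simulate.SimConfig(seed=seed, n_genes=n_genes, n_cases=n_cases,
                             n_controls=n_controls, case_adult_fraction=1.0)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    variants = simulate.gen_variants(cfg, {g: (rate, rate) for g in gene_ids})
    panels = pd.DataFrame({"gene_id": gene_ids, "panel": "childhood"})
    cohorts = simulate.gen_cohorts(cfg)
    bcfg = burden.BurdenConfig(scenarios=("lof",),
                               design=(("childhood", "case_adult"),))
    results = burden.run_burden(variants, panels, cohorts, bcfg)
    n_sig = int((results["p_adj"] < 0.05).sum()) if not results.empty else 0
    return {"fraction_fdr_significant": n_sig / n_genes, "n_genes": n_genes,
            "n_tested": len(results)}


# ---------------------------------------------------------------------------
# EWCE: null uniformity and planted-specificity power
# ---------------------------------------------------------------------------

def _ewce_universe(seed: int, n_genes: int, n_celltypes: int,
                   planted: simulate.ExpressionPlan | None = None):
    cfg = simulate.SimConfig(seed=seed, n_genes=n_genes, n_celltypes=n_celltypes)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    _, _, ct = simulate.gen_expression(cfg, gene_ids, planted)
    spec = expression.specificity_matrix(ct)
    cov_rng = substream(seed, "misc", 0)
    covariates = pd.DataFrame({
        "transcript_length": cov_rng.lognormal(8.0, 1.0, n_genes),
        "gc_content": cov_rng.uniform(0.3, 0.6, n_genes),
    }, index=gene_ids)
    return gene_ids, spec, covariates


def ewce_null_pvalues(seed: int, n_seeds: int = 200, n_boot: int = 500,
                      n_genes: int = 2000, n_celltypes: int = 12,
                      n_target: int = 50) -> np.ndarray:
    """Null p-values with target sets drawn by the matched sampler itself."""
    pvals = []
    for i in range(n_seeds):
        rep_seed = int(substream(seed, "misc", i + 1).integers(2 ** 31))
        gene_ids, spec, cov = _ewce_universe(rep_seed, n_genes, n_celltypes)
        cfg = ewce.EWCEConfig(n_boot=n_boot, seed=rep_seed)
        rng = substream(rep_seed, "ewce", 0)
        anchor = list(rng.choice(gene_ids, size=n_target, replace=False))
        draw = ewce.matched_bootstrap(anchor, gene_ids, cov,
                                      ewce.EWCEConfig(n_boot=100, seed=rep_seed))
        target = [gene_ids[j] for j in draw[0]]
        res = ewce.ewce_test(sorted(set(target)), spec, spec.columns[0], cfg,
                             covariates=cov)
        pvals.append(res.p)
    return np.asarray(pvals)


def ewce_null_ks(seed: int, **kwargs) -> dict:
    """Kolmogorov-Smirnov uniformity check of the EWCE null p-values."""
    pvals = ewce_null_pvalues(seed, **kwargs)
    ks = stats.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "n_seeds": len(pvals),
            "mean_p": float(pvals.mean())}


def ewce_power(seed: int, n_seeds: int = 50, n_boot: int = 1000,
               n_genes: int = 2000, n_celltypes: int = 12,
               n_target: int = 50, fold: float = 3.0) -> dict:
    """Fraction of seeds detecting a planted specificity fold (BH p<0.05)."""
    target_cell = f"celltype_{n_celltypes:02d}"
    hits = 0
    for i in range(n_seeds):
        rep_seed = int(substream(seed, "misc", 1000 + i).integers(2 ** 31))
        gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
        plan = simulate.ExpressionPlan(genes=tuple(gene_ids[:n_target]),
                                       cell_type=target_cell, fold=fold)
        gene_ids, spec, cov = _ewce_universe(rep_seed, n_genes, n_celltypes,
                                             planted=plan)
        cfg = ewce.EWCEConfig(n_boot=n_boot, seed=rep_seed)
        res = ewce.ewce_all(gene_ids[:n_target], spec, cfg, covariates=cov)
        res = ewce.adjust_over_grid(res)
        p_adj = res.loc[res["cell_type"] == target_cell, "p_adj"].item()
        hits += p_adj < 0.05
    return {"fraction_detected": hits / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# RFE: planted-feature recovery and permuted-label null
# ---------------------------------------------------------------------------

def planted_feature_data(seed: int, n_per_class: int = 200, n_features: int = 60,
                         n_informative: int = 5, effect: float = 1.5,
                         permute_labels: bool = False
                         ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Gaussian feature matrix with a mean shift on the informative columns."""
    rng = substream(seed, "selection", 0)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_features))
    X[:n_per_class, :n_informative] += effect
    y = np.array(["disease"] * n_per_class + ["control"] * n_per_class)
    if permute_labels:
        y = rng.permutation(y)
    idx = [f"g{i:04d}" for i in range(n)]
    cols = [f"f{j:02d}" for j in range(n_features)]
    return (pd.DataFrame(X, index=idx, columns=cols),
            pd.Series(y, index=idx), cols[:n_informative])


def rfe_recovery(seed: int, n_seeds: int = 20, repeats: int = 50, **data_kwargs) -> dict:
    """Fraction of seeds where every informative feature reaches frequency 0.8."""
    hits = 0
    for i in range(n_seeds):
        rep_seed = int(substream(seed, "misc", 2000 + i).integers(2 ** 31))
        X, y, informative = planted_feature_data(rep_seed, **data_kwargs)
        cfg = selection.RFEConfig(repeats=repeats, seed=rep_seed)
        report = selection.balanced_rfe(X, y, cfg)
        hits += bool((report.frequencies[informative] >= cfg.keep_frequency).all())
    return {"fraction_recovered": hits / n_seeds, "n_seeds": n_seeds}


def rfe_null(seed: int, n_seeds: int = 20, repeats: int = 50, **data_kwargs) -> dict:
    """Fraction of permuted-label seeds where no feature reaches frequency 0.8."""
    clean = 0
    for i in range(n_seeds):
        rep_seed = int(substream(seed, "misc", 3000 + i).integers(2 ** 31))
        X, y, _ = planted_feature_data(rep_seed, permute_labels=True, **data_kwargs)
        cfg = selection.RFEConfig(repeats=repeats, seed=rep_seed)
        report = selection.balanced_rfe(X, y, cfg)
        clean += bool((report.frequencies < cfg.keep_frequency).all())
    return {"fraction_clean": clean / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# STR tails: planted inflation detection and null centering
# ---------------------------------------------------------------------------

def _strtail_diffs(seed: int, inflation: float, n_cases: int, n_controls: int,
                   n_loci: int) -> list[float]:
    cfg = simulate.SimConfig(
        seed=seed, n_genes=30, n_cases=n_cases, n_controls=n_controls,
        case_adult_fraction=1.0,
        planted_effects={"tail_inflation_repeats": inflation},
    )
    genes, _, labels = simulate.gen_annotation(cfg)
    catalog = simulate.gen_str_catalog(genes, labels, cfg)[:n_loci]
    genotypes = simulate.gen_str_genotypes(catalog, cfg)
    tcfg = strtail.TailConfig()
    return [
        strtail.top_tail_compare(l.locus_id, genotypes, "case_adult", tcfg).difference
        for l in catalog
    ]


def strtail_detection(seed: int, n_seeds: int = 50, inflation: float = 10.0,
                      n_cases: int = 500, n_controls: int = 2000,
                      n_loci: int = 40) -> dict:
    """Fraction of seeds with a positive mean top-1% difference."""
    positive = 0
    for i in range(n_seeds):
        rep_seed = int(substream(seed, "misc", 4000 + i).integers(2 ** 31))
        diffs = _strtail_diffs(rep_seed, inflation, n_cases, n_controls, n_loci)
        positive += np.mean(diffs) > 0
    return {"fraction_positive": positive / n_seeds, "n_seeds": n_seeds}


def strtail_null(seed: int, n_seeds: int = 20, n_cases: int = 500,
                 n_controls: int = 2000, n_loci: int = 40) -> dict:
    """Pooled mean top-1% difference with no planted inflation."""
    means = []
    for i in range(n_seeds):
        rep_seed = int(substream(seed, "misc", 5000 + i).integers(2 ** 31))
        diffs = _strtail_diffs(rep_seed, 0.0, n_cases, n_controls, n_loci)
        means.append(np.mean(diffs))
    return {"pooled_mean_difference": float(np.mean(means)), "n_seeds": n_seeds}
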
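"""Synthetic inputs with planted statistical structure.

The generators emulate the study's inputs — gene models with
exon/intron/UTR structure, a HipSTR-style STR catalog with
class-dependent density, expression matrices with planted tissue and
cell-type specificity, case/control qualifying-variant tables with
planted carrier rates, and STR genotype tables with planted tail
inflation in cases — so that every downstream stage is testable with a
known ground truth.

Defaults mirror the study's conditions: four gene classes (adult-,
childhood-, overlap-onset and control), cohort sizes of 816 adult-onset
and 306 childhood-onset cases versus 6658 controls, a twofold STR density
elevation in disease-class genes (the study reports medians of 34.5 and
27 STRs per adult-/childhood-onset gene against 16 per control gene),
carrier rates of 6/816 in cases versus 7/6658 in controls (the observed
LoF burden for the top genes), and a +10 repeat-unit inflation applied to
1% of case alleles.

All randomness descends from ``SimConfig.seed`` via named sub-streams
(see :mod:`panelomics._rng`), so identical configs give byte-identical
outputs and each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from panelomics._rng import stream
from panelomics.annotation import GeneModel, RepeatElement, STRLocus, Transcript

PANEL_CLASSES = ("adult", "childhood", "overlap", "control")
DISEASE_CLASSES = ("adult", "childhood", "overlap")

_DEFAULT_FRACTIONS = {"adult": 0.05, "childhood": 0.50, "overlap": 0.20, "control": 0.25}
_DEFAULT_EFFECTS = {
    "str_density_ratio": 2.0,
    "specificity_fold": 3.0,
    "carrier_rate_case": 6 / 816,
    "carrier_rate_control": 7 / 6658,
    "tail_inflation_repeats": 10.0,
    "tail_fraction": 0.01,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Configuration of a synthetic study.

    ``panel_fractions`` must cover exactly the four onset classes and sum
    to 1.  ``planted_effects`` holds the effect magnitudes the generators
    plant (any omitted key falls back to the study default).
    """

    seed: int = 0
    n_genes: int = 400
    n_tissues: int = 12
    n_celltypes: int = 12
    n_cases: int = 1122          # 816 adult- + 306 childhood-onset probands
    n_controls: int = 6658
    case_adult_fraction: float = 816 / 1122
    panel_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    planted_effects: dict = field(default_factory=dict)
    mean_transcripts: float = 3.0
    mean_exons: float = 4.0
    mean_gene_length: float = 3000.0
    allow_overlapping_genes: bool = False
    str_per_kb: float = 2.0
    n_intergenic_strs: int = 10
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if set(self.panel_fractions) != set(PANEL_CLASSES):
            raise ConfigurationError(
                f"panel_fractions must cover exactly {PANEL_CLASSES}"
            )
        total = sum(self.panel_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"panel_fractions sum to {total}, expected 1")
        for name in ("n_genes", "n_tissues", "n_celltypes", "n_cases", "n_controls"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_tissues < 10:
            raise ConfigurationError("n_tissues must be >= 10")
        effects = dict(_DEFAULT_EFFECTS)
        effects.update(self.planted_effects)
        self.planted_effects = effects

    def effect(self, name: str) -> float:
        return float(self.planted_effects[name])


def panel_counts(config: SimConfig) -> dict[str, int]:
    """Genes per class by largest-remainder apportionment (exact when exact)."""
    raw = {c: config.panel_fractions[c] * config.n_genes for c in PANEL_CLASSES}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = config.n_genes - sum(counts.values())
    for c in sorted(PANEL_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


# ---------------------------------------------------------------------------
# gene models, sequence, labels
# ---------------------------------------------------------------------------

def _make_transcript(rng: np.random.Generator, tid: str, offset: int, length: int,
                     mean_exons: float, strand: str) -> Transcript:
    n_exons = 1 + rng.poisson(max(mean_exons - 1, 0))
    n_exons = min(n_exons, max(1, length // 100))
    if n_exons == 1:
        exons = [(offset, offset + length)]
    else:
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        exons = [(offset + int(bounds[2 * i]), offset + int(bounds[2 * i + 1]))
                 for i in range(n_exons)]
    exonic = sum(e - s for s, e in exons)
    cds: list[tuple[int, int]] = []
    left_utr: list[tuple[int, int]] = []
    right_utr: list[tuple[int, int]] = []
    if exonic >= 60:
        a5 = int(exonic * rng.uniform(0.10, 0.30))
        a3 = int(exonic * rng.uniform(0.70, 0.95))
        left_utr = _exonic_slice(exons, 0, a5)
        cds = _exonic_slice(exons, a5, a3)
        right_utr = _exonic_slice(exons, a3, exonic)
    utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
    return Transcript(tid, exons, cds, utr5, utr3)


def _exonic_slice(exons: list[tuple[int, int]], a: int, b: int) -> list[tuple[int, int]]:
    """Genomic intervals corresponding to exonic-coordinate range [a, b)."""
    out: list[tuple[int, int]] = []
    pos = 0
    for s, e in exons:
        ln = e - s
        lo, hi = max(a - pos, 0), min(b - pos, ln)
        if hi > lo:
            out.append((s + lo, s + hi))
        pos += ln
    return out


def gen_annotation(config: SimConfig) -> tuple[list[GeneModel], dict[str, str], pd.DataFrame]:
    """Generate gene models, the genome sequence and the panel label table.

    Returns ``(genes, genome, labels)`` where ``labels`` has one row per
    gene with columns ``gene_id``, ``panel`` and ``target_gc`` (the GC
    fraction the emitted sequence realizes to within rounding).
    """
    rng = stream(config.seed, "annotation")
    counts = panel_counts(config)
    panels = np.repeat(
        [c for c in PANEL_CLASSES], [counts[c] for c in PANEL_CLASSES]
    )
    rng.shuffle(panels)

    genes: list[GeneModel] = []
    records = []
    cursor = 1000
    for i in range(config.n_genes):
        length = max(600, int(rng.lognormal(math.log(config.mean_gene_length), 0.4)))
        gap = int(rng.integers(200, 1001))
        if config.allow_overlapping_genes and i > 0 and rng.random() < 0.2:
            start = max(0, cursor - gap - length // 2)
        else:
            start = cursor + gap
        gid = f"G{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = 1 + rng.poisson(max(config.mean_transcripts - 1, 0))
        transcripts = [
            _make_transcript(rng, f"{gid}.T{j + 1}", start, length,
                             config.mean_exons, strand)
            for j in range(n_tx)
        ]
        genes.append(GeneModel(gid, config.chrom, start, start + length,
                               strand, transcripts))
        target_gc = rng.uniform(0.35, 0.60)
        records.append({"gene_id": gid, "panel": panels[i], "target_gc": target_gc})
        cursor = start + length

    seq_rng = stream(config.seed, "sequence")
    chrom_len = cursor + 2000
    seq = np.empty(chrom_len, dtype="<U1")
    seq[:] = "N"
    # fill genes with the exact GC count for their target, then pad gaps
    for gene, rec in zip(genes, records):
        L = gene.length
        n_gc = int(round(L * rec["target_gc"]))
        bases = np.concatenate([
            seq_rng.choice(np.array(["G", "C"]), size=n_gc),
            seq_rng.choice(np.array(["A", "T"]), size=L - n_gc),
        ])
        seq_rng.shuffle(bases)
        seq[gene.start:gene.end] = bases
    gapmask = seq == "N"
    seq[gapmask] = seq_rng.choice(np.array(["A", "C", "G", "T"]), size=int(gapmask.sum()))
    genome = {config.chrom: "".join(seq)}
    labels = pd.DataFrame(records)
    return genes, genome, labels


# ---------------------------------------------------------------------------
# STR catalog
# ---------------------------------------------------------------------------

def gen_str_catalog(genes: list[GeneModel], labels: pd.DataFrame,
                    config: SimConfig) -> list[STRLocus]:
    """STR catalog with class-dependent density.

    Expected per-gene locus count is ``str_per_kb × length/1kb`` for
    control genes and ``str_density_ratio`` times that for disease-class
    genes.  Periods are drawn from {2..6}; reference repeat counts follow
    a shifted geometric (right-skewed, like empirical catalogs).
    """
    rng = stream(config.seed, "str_catalog")
    ratio = config.effect("str_density_ratio")
    panel = labels.set_index("gene_id")["panel"]
    loci: list[STRLocus] = []
    idx = 0
    for gene in genes:
        lam = config.str_per_kb * gene.length / 1000.0
        if panel[gene.gene_id] in DISEASE_CLASSES:
            lam *= ratio
        for _ in range(rng.poisson(lam)):
            period = int(rng.integers(2, 7))
            ref = 3 + int(rng.geometric(0.35))
            length = period * ref
            if length >= gene.length:
                ref = max(1, gene.length // period - 1)
                length = period * ref
            start = int(rng.integers(gene.start, gene.end - length))
            motif = "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=period))
            idx += 1
            loci.append(STRLocus(f"STR{idx:06d}", gene.chrom, start,
                                 start + length, period, ref, motif))
    if genes:
        tail = max(g.end for g in genes)
        for _ in range(config.n_intergenic_strs):
            period = int(rng.integers(2, 7))
            ref = 3 + int(rng.geometric(0.35))
            start = tail + 100 + int(rng.integers(0, 1500))
            idx += 1
            loci.append(STRLocus(f"STR{idx:06d}", config.chrom, start,
                                 start + period * ref, period, ref))
    return loci


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionPlan:
    """Which genes get planted specificity, where, and how strongly.

    The planted value in the target column is set to ``fold`` times the
    gene's mean over the background columns (with a small lognormal
    jitter), so the realized fold change matches the requested one.
    """

    genes: tuple = ()
    tissue: str | None = None
    cell_type: str | None = None
    fold: float = 1.0


def gen_expression(
    config: SimConfig,
    gene_ids: list[str],
    plan: ExpressionPlan | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(tissue expression, module membership, cell-type mean expression).

    All three outputs are keyed by ``gene_ids``.  Background columns are
    exchangeable; planted genes get ``plan.fold`` times their background
    mean in the target tissue / cell type.
    """
    plan = plan or ExpressionPlan()
    unknown = set(plan.genes) - set(gene_ids)
    if unknown:
        raise ValueError(f"plan references unknown genes: {sorted(unknown)[:5]}")

    tissues = [f"tissue_{i + 1:02d}" for i in range(config.n_tissues)]
    cells = [f"celltype_{i + 1:02d}" for i in range(config.n_celltypes)]
    n = len(gene_ids)

    rng = stream(config.seed, "expression")
    expr = pd.DataFrame(rng.lognormal(1.0, 0.2, size=(n, config.n_tissues)),
                        index=gene_ids, columns=tissues)
    if plan.tissue is not None and plan.fold != 1.0:
        if plan.tissue not in tissues:
            raise ValueError(f"unknown tissue {plan.tissue!r}")
        others = [t for t in tissues if t != plan.tissue]
        base = expr.loc[list(plan.genes), others].mean(axis=1)
        jitter = np.exp(rng.normal(0.0, 0.05, size=len(plan.genes)))
        expr.loc[list(plan.genes), plan.tissue] = plan.fold * base * jitter

    mm_rng = stream(config.seed, "module_membership")
    mm = pd.DataFrame(np.clip(mm_rng.normal(0.15, 0.2, size=(n, config.n_tissues)), -1, 1),
                      index=gene_ids, columns=tissues)
    if plan.tissue is not None and plan.fold != 1.0:
        mm.loc[list(plan.genes), plan.tissue] = mm_rng.uniform(0.75, 0.95, size=len(plan.genes))

    ct_rng = stream(config.seed, "celltype")
    ct = pd.DataFrame(ct_rng.lognormal(0.0, 0.2, size=(n, config.n_celltypes)),
                      index=gene_ids, columns=cells)
    if plan.cell_type is not None and plan.fold != 1.0:
        if plan.cell_type not in cells:
            raise ValueError(f"unknown cell type {plan.cell_type!r}")
        others = [c for c in cells if c != plan.cell_type]
        base = ct.loc[list(plan.genes), others].mean(axis=1)
        jitter = np.exp(ct_rng.normal(0.0, 0.05, size=len(plan.genes)))
        ct.loc[list(plan.genes), plan.cell_type] = plan.fold * base * jitter
    return expr, mm, ct


# ---------------------------------------------------------------------------
# cohorts, variants, STR genotypes
# ---------------------------------------------------------------------------

def gen_cohorts(config: SimConfig) -> pd.DataFrame:
    """Proband table: individual_id, cohort (case_adult/case_childhood/control)."""
    n_adult = int(round(config.n_cases * config.case_adult_fraction))
    rows = []
    for i in range(config.n_cases):
        cohort = "case_adult" if i < n_adult else "case_childhood"
        rows.append({"individual_id": f"P{i + 1:05d}", "cohort": cohort})
    for i in range(config.n_controls):
        rows.append({"individual_id": f"C{i + 1:05d}", "cohort": "control"})
    return pd.DataFrame(rows)


VARIANT_COLUMNS = ["proband_id", "cohort", "gene_id", "score", "lof", "ccr",
                   "de_novo", "de_novo_evaluable", "genotype", "maf", "moi"]


def gen_variants(config: SimConfig,
                 gene_rates: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Qualifying-variant table with Binomial carrier counts per gene.

    For each gene with rates ``(case_rate, control_rate)``, carrier counts
    are Binomial(n_cases, case_rate) and Binomial(n_controls,
    control_rate); carriers get at most one qualifying variant per gene
    (dominant model).  Emitted rows pass the dominant rare-variant filter
    (MAF < 0.1%) and carry a high pathogenicity score plus LoF/CCR/de-novo
    flags.
    """
    rng = stream(config.seed, "variants")
    cohorts = gen_cohorts(config)
    cases = cohorts[cohorts["cohort"] != "control"].reset_index(drop=True)
    controls = cohorts[cohorts["cohort"] == "control"].reset_index(drop=True)
    rows = []
    for gene_id in sorted(gene_rates):
        case_rate, control_rate = gene_rates[gene_id]
        for r in (case_rate, control_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"carrier rate {r} for {gene_id} outside [0, 1]")
        for pool, rate in ((cases, case_rate), (controls, control_rate)):
            k = rng.binomial(len(pool), rate)
            if k == 0:
                continue
            picks = rng.choice(len(pool), size=k, replace=False)
            for j in sorted(picks):
                rows.append({
                    "proband_id": pool.loc[j, "individual_id"],
                    "cohort": pool.loc[j, "cohort"],
                    "gene_id": gene_id,
                    "score": rng.uniform(0.85, 1.0),
                    "lof": True,
                    "ccr": bool(rng.random() < 0.3),
                    "de_novo": bool(rng.random() < 0.1),
                    "de_novo_evaluable": bool(rng.random() < 0.4),
                    "genotype": "het",
                    "maf": rng.uniform(0.0, 0.0009),
                    "moi": "dominant",
                })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def gen_str_genotypes(catalog: list[STRLocus], config: SimConfig) -> pd.DataFrame:
    """Per-individual STR genotypes with planted case tail inflation.

    Baseline alleles are the catalog reference repeat count plus a
    discretized negative-binomial jitter (right-skewed, floored at 1
    repeat).  A fraction ``tail_fraction`` of case alleles is inflated by
    ``tail_inflation_repeats``; control alleles are never inflated.
    """
    if not catalog:
        raise ValueError("catalog must be nonempty")
    rng = stream(config.seed, "str_genotypes")
    cohorts = gen_cohorts(config)
    n_ind, n_loci = len(cohorts), len(catalog)
    refs = np.array([round(l.ref_repeats) for l in catalog], dtype=int)

    # NB(2, 0.5) has mean 2; centering at the reference keeps the mode there
    jitter = rng.negative_binomial(2, 0.5, size=(n_ind, n_loci, 2)) - 2
    alleles = np.maximum(refs[None, :, None] + jitter, 1)

    inflation = int(round(config.effect("tail_inflation_repeats")))
    frac = config.effect("tail_fraction")
    case_mask = (cohorts["cohort"] != "control").to_numpy()
    if inflation != 0 and frac > 0:
        hit = rng.random(size=(n_ind, n_loci, 2)) < frac
        hit &= case_mask[:, None, None]
        alleles = alleles + inflation * hit

    ind = np.repeat(cohorts["individual_id"].to_numpy(), n_loci)
    coh = np.repeat(cohorts["cohort"].to_numpy(), n_loci)
    loc = np.tile(np.array([l.locus_id for l in catalog]), n_ind)
    return pd.DataFrame({
        "individual_id": ind,
        "cohort": coh,
        "locus_id": loc,
        "allele1": alleles[:, :, 0].ravel(),
        "allele2": alleles[:, :, 1].ravel(),
    })


# ---------------------------------------------------------------------------
# repetitive elements and CNCR segments (inputs to the feature table)
# ---------------------------------------------------------------------------

def gen_repeat_elements(genes: list[GeneModel], labels: pd.DataFrame,
                        config: SimConfig, density_ratio: float = 1.5,
                        per_kb: float = 0.5) -> list[RepeatElement]:
    """RepeatMasker-style elements with a mild disease-class excess."""
    rng = stream(config.seed, "repeats")
    panel = labels.set_index("gene_id")["panel"]
    families = np.array(["LINE/L1", "SINE/Alu", "Retroposon/SVA"])
    out: list[RepeatElement] = []
    for gene in genes:
        lam = per_kb * gene.length / 1000.0
        if panel[gene.gene_id] in DISEASE_CLASSES:
            lam *= density_ratio
        for _ in range(rng.poisson(lam)):
            length = int(rng.integers(100, 500))
            start = int(rng.integers(gene.start, max(gene.start + 1, gene.end - length)))
            out.append(RepeatElement(str(rng.choice(families)), gene.chrom,
                                     start, start + length))
    return out


def gen_cncr_segments(genes: list[GeneModel], labels: pd.DataFrame,
                      config: SimConfig, disease_density: float = 0.15,
                      control_density: float = 0.08) -> list[tuple[str, int, int]]:
    """CNCR intervals covering a class-dependent fraction of each gene."""
    rng = stream(config.seed, "cncr")
    panel = labels.set_index("gene_id")["panel"]
    out: list[tuple[str, int, int]] = []
    for gene in genes:
        target = disease_density if panel[gene.gene_id] in DISEASE_CLASSES else control_density
        covered = 0
        budget = target * gene.length
        while covered < budget:
            length = int(rng.integers(50, 200))
            start = int(rng.integers(gene.start, max(gene.start + 1, gene.end - length)))
            out.append((gene.chrom, start, min(start + length, gene.end)))
            covered += length
    return out
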
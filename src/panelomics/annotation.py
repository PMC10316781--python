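"""Gene models, interval arithmetic and per-gene genomic features.

Internal coordinates are 0-based half-open throughout.  GTF is read and
written as 1-based inclusive; the HipSTR-dialect STR BED is read as
0-based start with *inclusive* end (converted to half-open on load), with
``one_based=True`` available for catalogs that use 1-based starts.

Feature computation covers gene structure and complexity (length,
transcript count, exon-exon junctions, GC content), short tandem repeat
(STR) density by period and genic context, eSTR counts, RepeatMasker-style
repetitive-element counts (LINE/L1, SINE/Alu, retroposon/SVA) and the
per-gene density of constrained non-conserved regions (CNCRs) — the
fraction of the gene span covered by the base-level union of CNCR
segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Interval = tuple[int, int]

CONTEXTS = ("coding_exon", "five_prime_utr", "three_prime_utr", "intron", "intergenic")
#: precedence for a locus overlapping several annotation classes
CONTEXT_PRECEDENCE = ("coding_exon", "five_prime_utr", "three_prime_utr", "intron")

REPEAT_FAMILIES = ("LINE/L1", "SINE/Alu", "Retroposon/SVA")


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def _check_interval(iv: Interval) -> None:
    if iv[0] >= iv[1]:
        raise ValueError(f"malformed interval {iv}: start must be < end")


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Base-level union of half-open intervals, as sorted disjoint intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        _check_interval((s, e))
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def covered_length(intervals: Iterable[Interval], window: Interval | None = None) -> int:
    """Length of the base-level union, optionally clipped to ``window``."""
    total = 0
    for s, e in merge_intervals(intervals):
        if window is not None:
            s, e = max(s, window[0]), min(e, window[1])
        if e > s:
            total += e - s
    return total


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval]                       # sorted, non-overlapping
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has 0 exons")
        self.exons = sorted(self.exons)
        for iv in self.exons:
            _check_interval(iv)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt[0] < prev[1]:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons {prev} and {nxt}"
                )

    @property
    def junctions(self) -> list[Interval]:
        """(donor, acceptor) coordinate pairs: (end of exon i, start of exon i+1)."""
        return [(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        _check_interval((self.start, self.end))
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for tx in self.transcripts:
            for s, e in tx.exons:
                if s < self.start or e > self.end:
                    raise ValueError(
                        f"gene {self.gene_id}: exon ({s},{e}) outside span "
                        f"({self.start},{self.end})"
                    )

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class STRLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    period: int
    ref_repeats: float
    motif: str | None = None
    context: str | None = None
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_interval((self.start, self.end))
        if self.period < 1:
            raise ValueError(f"STR {self.locus_id}: period must be >= 1")


@dataclass
class RepeatElement:
    family: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        _check_interval((self.start, self.end))


# ---------------------------------------------------------------------------
# overlap counting
# ---------------------------------------------------------------------------

def count_overlaps(
    intervals: Sequence[tuple[str, int, int]],
    genes: Sequence[GeneModel],
) -> pd.Series:
    """Count intervals overlapping each gene span (any overlap, both genes count).

    An interval overlapping k genes contributes 1 to each of them; an
    interval overlapping no gene contributes nowhere.
    """
    counts = pd.Series(0, index=[g.gene_id for g in genes], dtype=int)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, s, e in intervals:
        _check_interval((s, e))
        for g in by_chrom.get(chrom, ()):
            if overlaps((s, e), g.span):
                counts[g.gene_id] += 1
    return counts


def assign_genes(loci: Iterable[STRLocus], genes: Sequence[GeneModel]) -> None:
    """Set ``gene_ids`` on each locus to every gene whose span it overlaps."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for locus in loci:
        locus.gene_ids = [
            g.gene_id
            for g in by_chrom.get(locus.chrom, ())
            if overlaps((locus.start, locus.end), g.span)
        ]


# ---------------------------------------------------------------------------
# STR context classification
# ---------------------------------------------------------------------------

def classify_str_context(locus: STRLocus, gene: GeneModel) -> str:
    """Context of a locus within a gene by precedence over the transcript union.

    coding_exon > five_prime_utr > three_prime_utr > intron; a locus
    overlapping no exonic part of any transcript is intronic.  Exons of a
    transcript without an annotated CDS count as coding_exon.
    """
    iv = (locus.start, locus.end)
    if locus.chrom != gene.chrom or not overlaps(iv, gene.span):
        raise ValueError(
            f"locus {locus.locus_id} does not overlap gene {gene.gene_id}"
        )
    hit = {c: False for c in CONTEXT_PRECEDENCE}
    for tx in gene.transcripts:
        coding = tx.cds if tx.cds else tx.exons
        hit["coding_exon"] |= any(overlaps(iv, c) for c in coding)
        hit["five_prime_utr"] |= any(overlaps(iv, u) for u in tx.utr5)
        hit["three_prime_utr"] |= any(overlaps(iv, u) for u in tx.utr3)
    for ctx in CONTEXT_PRECEDENCE[:-1]:
        if hit[ctx]:
            return ctx
    return "intron"


def annotate_catalog(loci: Iterable[STRLocus], genes: Sequence[GeneModel]) -> list[STRLocus]:
    """Assign gene_ids and the highest-precedence context to each locus."""
    loci = list(loci)
    assign_genes(loci, genes)
    gene_map = {g.gene_id: g for g in genes}
    rank = {c: i for i, c in enumerate(CONTEXT_PRECEDENCE)}
    for locus in loci:
        if not locus.gene_ids:
            locus.context = "intergenic"
            continue
        ctxs = [classify_str_context(locus, gene_map[g]) for g in locus.gene_ids]
        locus.context = min(ctxs, key=lambda c: rank[c])
    return loci


# ---------------------------------------------------------------------------
# per-gene features
# ---------------------------------------------------------------------------

def str_features(gene: GeneModel, catalog: Sequence[STRLocus]) -> dict[str, float]:
    """STR counts (total, per period 2-6, per context) and length statistics."""
    mine = [
        l for l in catalog
        if l.chrom == gene.chrom and overlaps((l.start, l.end), gene.span)
    ]
    out: dict[str, float] = {"n_strs": len(mine)}
    for p in range(2, 7):
        out[f"n_strs_period_{p}"] = sum(l.period == p for l in mine)
    for ctx in CONTEXT_PRECEDENCE:
        out[f"n_strs_{ctx}"] = sum(
            classify_str_context(l, gene) == ctx for l in mine
        )
    lengths = [l.end - l.start for l in mine]
    out["str_total_bases"] = float(sum(lengths))
    out["str_mean_length"] = float(np.mean(lengths)) if lengths else 0.0
    return out


def estr_features(gene_id: str, estr_table: pd.DataFrame) -> tuple[int, int]:
    """(number of eSTRs, number of distinct tissues) for a gene.

    ``estr_table`` columns: locus_id, gene_id, tissues (comma-separated).
    Duplicate rows for a locus are collapsed; a gene absent from the table
    gets (0, 0).
    """
    rows = estr_table[estr_table["gene_id"] == gene_id]
    if rows.empty:
        return 0, 0
    rows = rows.drop_duplicates(subset="locus_id")
    tissues: set[str] = set()
    for t in rows["tissues"]:
        tissues.update(x for x in str(t).split(",") if x)
    return len(rows), len(tissues)


def cncr_density(gene: GeneModel, segments: Sequence[tuple[str, int, int]]) -> float:
    """Fraction of the gene span covered by the union of CNCR segments."""
    if gene.length <= 0:
        raise ValueError(f"gene {gene.gene_id} has zero length")
    ivs = [(s, e) for chrom, s, e in segments if chrom == gene.chrom]
    if not ivs:
        return 0.0
    return covered_length(ivs, window=gene.span) / gene.length


def gc_content(seq: str) -> float | None:
    """(G+C)/(A+C+G+T), case-insensitive; ambiguous bases excluded. None if empty."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def structure_features(gene: GeneModel, genome: dict[str, str] | None = None) -> dict[str, float]:
    """gene_length, n_transcripts, n_junctions and (if sequence given) gc_content.

    n_junctions counts unique (donor, acceptor) coordinate pairs over all
    transcripts of the gene.
    """
    junctions = {j for tx in gene.transcripts for j in tx.junctions}
    out: dict[str, float] = {
        "gene_length": gene.length,
        "n_transcripts": len(gene.transcripts),
        "n_junctions": len(junctions),
    }
    if genome is not None and gene.chrom in genome:
        gc = gc_content(genome[gene.chrom][gene.start:gene.end])
        if gc is not None:
            out["gc_content"] = gc
    return out


def repeat_features(gene: GeneModel, elements: Sequence[RepeatElement]) -> dict[str, int]:
    """Counts of repetitive elements overlapping the gene span, per family."""
    keys = {"LINE/L1": "n_line_l1", "SINE/Alu": "n_sine_alu", "Retroposon/SVA": "n_sva"}
    out = {v: 0 for v in keys.values()}
    for el in elements:
        if el.chrom == gene.chrom and overlaps((el.start, el.end), gene.span):
            key = keys.get(el.family)
            if key:
                out[key] += 1
    return out


def build_feature_table(
    genes: Sequence[GeneModel],
    catalog: Sequence[STRLocus] = (),
    estr_table: pd.DataFrame | None = None,
    repeat_elements: Sequence[RepeatElement] = (),
    cncr_segments: Sequence[tuple[str, int, int]] = (),
    genome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene feature table (genes as rows, features as columns)."""
    rows = []
    for gene in genes:
        row: dict[str, float] = {"gene_id": gene.gene_id}
        row.update(structure_features(gene, genome))
        row.update(str_features(gene, catalog))
        if estr_table is not None:
            n_estrs, n_tissues = estr_features(gene.gene_id, estr_table)
            row["n_estrs"], row["n_estr_tissues"] = n_estrs, n_tissues
        row.update(repeat_features(gene, repeat_elements))
        row["cncr_density"] = (
            cncr_density(gene, cncr_segments) if cncr_segments else 0.0
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


FEATURE_CATEGORIES = {
    "gene_length": "structure", "n_transcripts": "structure",
    "n_junctions": "structure", "gc_content": "structure",
    "n_estrs": "repeat", "n_estr_tissues": "repeat",
    "n_line_l1": "repeat", "n_sine_alu": "repeat", "n_sva": "repeat",
    "cncr_density": "conservation",
}


def feature_metadata(table: pd.DataFrame) -> pd.DataFrame:
    """Sidecar: feature name, category and dtype for every column."""
    recs = []
    for col in table.columns:
        cat = FEATURE_CATEGORIES.get(col, "repeat" if col.startswith(("n_strs", "str_")) else "other")
        dtype = "numeric" if pd.api.types.is_numeric_dtype(table[col]) else "categorical"
        recs.append({"feature": col, "category": cat, "dtype": dtype})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (1-based inclusive coordinates)."""
    def line(chrom, feat, s, e, strand, attrs):
        a = " ".join(f'{k} "{v}";' for k, v in attrs)
        return f"{chrom}\tpanelomics\t{feat}\t{s + 1}\t{e}\t.\t{strand}\t.\t{a}\n"

    with open(path, "w") as fh:
        for g in genes:
            fh.write(line(g.chrom, "gene", g.start, g.end, g.strand, [("gene_id", g.gene_id)]))
            for tx in g.transcripts:
                attrs = [("gene_id", g.gene_id), ("transcript_id", tx.transcript_id)]
                ts = min(s for s, _ in tx.exons)
                te = max(e for _, e in tx.exons)
                fh.write(line(g.chrom, "transcript", ts, te, g.strand, attrs))
                for s, e in tx.exons:
                    fh.write(line(g.chrom, "exon", s, e, g.strand, attrs))
                for s, e in tx.cds:
                    fh.write(line(g.chrom, "CDS", s, e, g.strand, attrs))
                for s, e in tx.utr5:
                    fh.write(line(g.chrom, "five_prime_utr", s, e, g.strand, attrs))
                for s, e in tx.utr3:
                    fh.write(line(g.chrom, "three_prime_utr", s, e, g.strand, attrs))


def _parse_attrs(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read a GTF (1-based inclusive) into gene models (0-based half-open)."""
    genes: dict[str, dict] = {}
    txs: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            chrom, _, feat, s1, e1, _, strand, _, attr_field = raw.rstrip("\n").split("\t")
            s, e = int(s1) - 1, int(e1)  # to 0-based half-open
            attrs = _parse_attrs(attr_field)
            gid = attrs["gene_id"]
            if feat == "gene":
                genes[gid] = {"chrom": chrom, "start": s, "end": e, "strand": strand}
            elif feat in ("exon", "CDS", "five_prime_utr", "three_prime_utr"):
                tid = attrs["transcript_id"]
                tx = txs.setdefault((gid, tid), {"exons": [], "cds": [], "utr5": [], "utr3": []})
                key = {"exon": "exons", "CDS": "cds",
                       "five_prime_utr": "utr5", "three_prime_utr": "utr3"}[feat]
                tx[key].append((s, e))
    out = []
    for gid, info in genes.items():
        transcripts = [
            Transcript(tid, sorted(tx["exons"]), sorted(tx["cds"]),
                       sorted(tx["utr5"]), sorted(tx["utr3"]))
            for (g, tid), tx in sorted(txs.items()) if g == gid
        ]
        out.append(GeneModel(gid, info["chrom"], info["start"], info["end"],
                             info["strand"], transcripts))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_str_bed(loci: Sequence[STRLocus], path: str | Path) -> None:
    """Write a HipSTR-dialect BED: 0-based start, inclusive end."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end - 1}\t{l.period}\t{l.ref_repeats:g}\t{l.locus_id}\n")


def read_str_bed(path: str | Path, one_based: bool = False) -> list[STRLocus]:
    """Read a HipSTR-dialect BED (chrom, start, end, period, n_repeats, name).

    Default dialect: 0-based start, inclusive end (converted to half-open).
    ``one_based=True`` shifts starts down by one for 1-based catalogs.
    """
    loci = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith(("#", "track")):
                continue
            chrom, s, e, period, nrep, name = raw.rstrip("\n").split("\t")[:6]
            start = int(s) - (1 if one_based else 0)
            loci.append(STRLocus(name, chrom, start, int(e) + 1, int(period), float(nrep)))
    return loci


def read_rmsk(path: str | Path) -> list[RepeatElement]:
    """RepeatMasker-style TSV with columns chrom, start, end, family."""
    df = pd.read_csv(path, sep="\t")
    return [RepeatElement(r.family, r.chrom, int(r.start), int(r.end))
            for r in df.itertuples()]


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith(("#", "track")):
                continue
            chrom, s, e = raw.split("\t")[:3]
            out.append((chrom, int(s), int(e)))
    return out


def write_bed3(segments: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in segments:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write features TSV plus a ``<path>.meta.tsv`` metadata sidecar."""
    path = Path(path)
    table.to_csv(path, sep="\t")
    feature_metadata(table).to_csv(path.with_suffix(path.suffix + ".meta.tsv"),
                                   sep="\t", index=False)
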
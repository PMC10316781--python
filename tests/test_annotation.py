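"""Interval arithmetic, context classification and per-gene features."""

import numpy as np
import pandas as pd
import pytest

from panelomics import annotation
from panelomics.annotation import (
    GeneModel,
    STRLocus,
    Transcript,
    classify_str_context,
    cncr_density,
    count_overlaps,
    estr_features,
    gc_content,
    str_features,
    structure_features,
)


# --- independent per-base oracles -----------------------------------------

def brute_overlap_count(intervals, gene):
    """Count intervals sharing >= 1 base with the gene span, by base scan."""
    gs, ge = gene.start, gene.end
    count = 0
    for chrom, s, e in intervals:
        if chrom != gene.chrom:
            continue
        if any(gs <= pos < ge for pos in range(s, e)):
            count += 1
    return count


def brute_union_in_window(segments, chrom, window):
    covered = set()
    for c, s, e in segments:
        if c != chrom:
            continue
        covered.update(range(max(s, window[0]), min(e, window[1])))
    return len(covered)


def random_instance(rng, n_genes_max=10, n_iv_max=50, span=600):
    genes = []
    cursor = 0
    for i in range(rng.integers(1, n_genes_max + 1)):
        start = cursor + int(rng.integers(0, 30))
        length = int(rng.integers(20, 80))
        genes.append(GeneModel(f"g{i}", "c", start, start + length, "+",
                               [Transcript(f"g{i}.t", [(start, start + length)])]))
        # occasionally overlap the next gene with this one
        cursor = start + (length // 2 if rng.random() < 0.3 else length)
    intervals = []
    for _ in range(rng.integers(0, n_iv_max + 1)):
        s = int(rng.integers(0, span))
        intervals.append(("c", s, s + int(rng.integers(1, 40))))
    return genes, intervals


def test_count_overlaps_matches_per_base_scan_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(40):
        genes, intervals = random_instance(rng)
        counts = count_overlaps(intervals, genes)
        for gene in genes:
            assert counts[gene.gene_id] == brute_overlap_count(intervals, gene)


def test_count_overlaps_examples():
    g = GeneModel("g", "c", 100, 200, "+", [Transcript("t", [(100, 200)])])
    assert count_overlaps([("c", 150, 160), ("c", 300, 310)], [g])["g"] == 1
    assert count_overlaps([], [g])["g"] == 0
    a = GeneModel("A", "c", 0, 100, "+", [Transcript("ta", [(0, 100)])])
    b = GeneModel("B", "c", 50, 150, "+", [Transcript("tb", [(50, 150)])])
    counts = count_overlaps([("c", 60, 70)], [a, b])
    assert counts["A"] == 1 and counts["B"] == 1
    with pytest.raises(ValueError, match="malformed"):
        count_overlaps([("c", 10, 10)], [g])


def test_cncr_density_matches_per_base_scan_and_examples():
    g = GeneModel("g", "c", 0, 100, "+", [Transcript("t", [(0, 100)])])
    assert cncr_density(g, [("c", 10, 20), ("c", 15, 30)]) == pytest.approx(0.2)
    assert cncr_density(g, []) == 0.0
    assert cncr_density(g, [("c", 0, 100)]) == 1.0
    rng = np.random.default_rng(3)
    for _ in range(40):
        genes, intervals = random_instance(rng)
        for gene in genes:
            expected = brute_union_in_window(intervals, "c", gene.span) / gene.length
            assert cncr_density(gene, intervals) == pytest.approx(expected)


def test_cncr_density_invariant_under_order_and_splitting():
    g = GeneModel("g", "c", 0, 1000, "+", [Transcript("t", [(0, 1000)])])
    segs = [("c", 100, 300), ("c", 250, 400), ("c", 700, 750)]
    base = cncr_density(g, segs)
    assert cncr_density(g, segs[::-1]) == pytest.approx(base)
    split = [("c", 100, 200), ("c", 200, 300), ("c", 250, 400), ("c", 700, 720),
             ("c", 720, 750)]
    assert cncr_density(g, split) == pytest.approx(base)
    with pytest.raises(ValueError, match="zero length"):
        bad = GeneModel("z", "c", 0, 1, "+", [Transcript("t", [(0, 1)])])
        bad.end = 0  # force degenerate span
        cncr_density(bad, segs)


class TestContextClassification:
    def test_intronic_locus(self, toy_gene):
        only_t1 = GeneModel("G1", "chr1", 100, 400, "+", [toy_gene.transcripts[0]])
        locus = STRLocus("s", "chr1", 210, 240, 3, 10)
        assert classify_str_context(locus, only_t1) == "intron"

    def test_locus_spanning_exon_and_intron_is_coding(self, toy_gene):
        only_t1 = GeneModel("G1", "chr1", 100, 400, "+", [toy_gene.transcripts[0]])
        locus = STRLocus("s", "chr1", 180, 220, 2, 20)
        assert classify_str_context(locus, only_t1) == "coding_exon"

    def test_union_over_transcripts_prefers_utr_over_intron(self):
        # 5'UTR in transcript 1, intronic in transcript 2
        t1 = Transcript("T1", exons=[(0, 100)], cds=[(50, 100)], utr5=[(0, 50)])
        t2 = Transcript("T2", exons=[(200, 300)], cds=[(200, 300)])
        gene = GeneModel("G", "chr1", 0, 300, "+", [t1, t2])
        locus = STRLocus("s", "chr1", 10, 30, 3, 6)
        assert classify_str_context(locus, gene) == "five_prime_utr"

    def test_no_overlap_is_contract_violation(self, toy_gene):
        locus = STRLocus("s", "chr1", 500, 520, 2, 10)
        with pytest.raises(ValueError, match="does not overlap"):
            classify_str_context(locus, toy_gene)

    def test_precedence_order(self, toy_gene):
        # locus covering 5'UTR and CDS -> coding wins
        locus = STRLocus("s", "chr1", 140, 160, 2, 10)
        assert classify_str_context(locus, toy_gene) == "coding_exon"


def test_str_features_counts_and_partition(toy_gene):
    loci = [
        STRLocus("a", "chr1", 110, 122, 3, 4),
        STRLocus("b", "chr1", 160, 172, 3, 4),
        STRLocus("c", "chr1", 360, 372, 4, 3),
        STRLocus("far", "chr1", 900, 912, 3, 4),
    ]
    out = str_features(toy_gene, loci)
    assert out["n_strs"] == 3
    assert out["n_strs_period_3"] == 2
    assert out["n_strs_period_4"] == 1
    ctx_total = sum(out[f"n_strs_{c}"] for c in
                    ("coding_exon", "five_prime_utr", "three_prime_utr", "intron"))
    assert ctx_total == out["n_strs"]
    period_total = sum(out[f"n_strs_period_{p}"] for p in range(2, 7))
    assert period_total == out["n_strs"]
    empty = str_features(toy_gene, [])
    assert empty["n_strs"] == 0 and empty["str_mean_length"] == 0.0


def test_estr_features_set_union_and_dedup(estr_table):
    n, t = estr_features("GA", estr_table)
    assert (n, t) == (2, 2)  # L2 duplicated, tissues {brain, blood}
    assert estr_features("missing", estr_table) == (0, 0)


def test_structure_features_junctions_and_gc():
    t1 = Transcript("T1", exons=[(0, 10), (20, 30), (40, 50)])
    t2 = Transcript("T2", exons=[(0, 10), (20, 30)])
    g = GeneModel("G", "c", 0, 50, "+", [t1, t2])
    out = structure_features(g)
    assert out["n_junctions"] == 2      # {(10,20),(30,40)} shared pair counted once
    assert out["n_transcripts"] == 2
    single = GeneModel("S", "c", 0, 10, "+", [Transcript("t", [(0, 10)])])
    assert structure_features(single)["n_junctions"] == 0
    assert gc_content("GGCC") == 1.0
    assert gc_content("GGNNcc") == 1.0  # ambiguous bases excluded
    assert gc_content("NNN") is None
    with pytest.raises(ValueError, match="0 exons"):
        Transcript("bad", exons=[])


def test_gtf_round_trip_is_identity(small_sim, tmp_path):
    genes = small_sim["genes"]
    path = tmp_path / "genes.gtf"
    annotation.write_gtf(genes, path)
    back = annotation.read_gtf(path)
    assert len(back) == len(genes)
    by_id = {g.gene_id: g for g in back}
    for g in genes:
        b = by_id[g.gene_id]
        assert (b.chrom, b.start, b.end, b.strand) == (g.chrom, g.start, g.end, g.strand)
        orig = sorted(g.transcripts, key=lambda t: t.transcript_id)
        for to, tb in zip(orig, b.transcripts):
            assert to.exons == tb.exons
            assert to.cds == tb.cds
            assert to.utr5 == tb.utr5 and to.utr3 == tb.utr3
    # second round trip gives byte-identical GTF
    path2 = tmp_path / "again.gtf"
    annotation.write_gtf(sorted(back, key=lambda g: g.gene_id), path2)
    annotation.write_gtf(sorted(genes, key=lambda g: g.gene_id), path)
    assert path.read_bytes() == path2.read_bytes()


def test_str_bed_round_trip_and_one_based_flag(tmp_path):
    loci = [STRLocus("L1", "c", 10, 22, 3, 4.0), STRLocus("L2", "c", 100, 110, 2, 5.0)]
    path = tmp_path / "strs.bed"
    annotation.write_str_bed(loci, path)
    back = annotation.read_str_bed(path)
    assert [(l.start, l.end, l.period, l.ref_repeats) for l in back] == \
        [(10, 22, 3, 4.0), (100, 110, 2, 5.0)]
    shifted = annotation.read_str_bed(path, one_based=True)
    assert [l.start for l in shifted] == [9, 99]


def test_feature_table_and_metadata(small_sim, tmp_path):
    genes = small_sim["genes"][:10]
    table = annotation.build_feature_table(genes, small_sim["catalog"],
                                           genome=small_sim["genome"])
    assert list(table.index) == [g.gene_id for g in genes]
    assert (table["n_strs"] >= 0).all()
    assert table["cncr_density"].between(0, 1).all()
    annotation.write_feature_table(table, tmp_path / "feat.tsv")
    meta = pd.read_csv(tmp_path / "feat.tsv.meta.tsv", sep="\t")
    assert set(meta["feature"]) == set(table.columns)
    assert set(meta["dtype"]) <= {"numeric", "categorical"}
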
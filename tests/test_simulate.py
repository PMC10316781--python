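"""Determinism, conservation and planted-effect behavior of the generators."""

import numpy as np
import pandas as pd
import pytest

from panelomics import annotation, comparison, expression, simulate
from panelomics.simulate import ConfigurationError, ExpressionPlan, SimConfig


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum"):
            SimConfig(panel_fractions={"adult": 0.5, "childhood": 0.5,
                                       "overlap": 0.5, "control": 0.5})

    def test_fractions_must_cover_all_classes(self):
        with pytest.raises(ConfigurationError, match="cover"):
            SimConfig(panel_fractions={"adult": 0.5, "childhood": 0.5})

    def test_counts_positive_and_tissue_minimum(self):
        with pytest.raises(ConfigurationError, match="positive"):
            SimConfig(n_genes=0)
        with pytest.raises(ConfigurationError, match=">= 10"):
            SimConfig(n_tissues=8)

    def test_rounding_free_panel_counts(self):
        cfg = SimConfig(n_genes=100, panel_fractions={
            "adult": 0.05, "childhood": 0.5, "overlap": 0.2, "control": 0.25})
        assert simulate.panel_counts(cfg) == {
            "adult": 5, "childhood": 50, "overlap": 20, "control": 25}


class TestAnnotationGenerator:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=11, n_genes=40)
        for run in ("a", "b"):
            genes, genome, labels = simulate.gen_annotation(cfg)
            annotation.write_gtf(genes, tmp_path / f"{run}.gtf")
            annotation.write_fasta(genome, tmp_path / f"{run}.fa")
            labels.to_csv(tmp_path / f"{run}.tsv", sep="\t", index=False)
        for ext in ("gtf", "fa", "tsv"):
            assert (tmp_path / f"a.{ext}").read_bytes() == (tmp_path / f"b.{ext}").read_bytes()

    def test_conservation_and_label_coverage(self, small_sim):
        cfg, genes, labels = (small_sim["config"], small_sim["genes"],
                              small_sim["labels"])
        assert len(genes) == cfg.n_genes
        assert labels["gene_id"].is_unique
        assert set(labels["gene_id"]) == {g.gene_id for g in genes}
        counts = labels["panel"].value_counts().to_dict()
        assert counts == simulate.panel_counts(cfg)

    def test_every_gene_has_transcripts_with_exons(self, small_sim):
        for g in small_sim["genes"]:
            assert g.transcripts
            for tx in g.transcripts:
                assert tx.exons

    def test_gc_content_matches_target_within_two_percent(self, small_sim):
        genome = small_sim["genome"]
        targets = small_sim["labels"].set_index("gene_id")["target_gc"]
        for g in small_sim["genes"]:
            seq = genome[g.chrom][g.start:g.end]
            gc = annotation.gc_content(seq)
            assert abs(gc - targets[g.gene_id]) < 0.02

    def test_transcript_count_mean_within_ten_percent(self):
        cfg = SimConfig(seed=5, n_genes=500, mean_transcripts=3.0)
        genes, _, _ = simulate.gen_annotation(cfg)
        mean_tx = np.mean([len(g.transcripts) for g in genes])
        assert abs(mean_tx - 3.0) / 3.0 < 0.10


class TestSTRCatalog:
    def test_empty_gene_list_gives_empty_catalog(self):
        cfg = SimConfig(seed=1)
        assert simulate.gen_str_catalog([], pd.DataFrame(columns=["gene_id", "panel"]),
                                        cfg) == []

    def test_records_carry_required_fields(self, small_sim):
        for locus in small_sim["catalog"]:
            assert locus.period in range(2, 7)
            assert locus.end > locus.start
            assert locus.ref_repeats >= 1

    def test_null_density_ratio_indistinguishable_classes(self):
        """ratio=1: disease and control STR counts from one distribution."""
        insignificant = 0
        fractions = {"adult": 0.0, "childhood": 0.5, "overlap": 0.0, "control": 0.5}
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_genes=120, panel_fractions=fractions,
                            planted_effects={"str_density_ratio": 1.0})
            genes, _, labels = simulate.gen_annotation(cfg)
            catalog = simulate.gen_str_catalog(genes, labels, cfg)
            counts = annotation.count_overlaps(
                [(l.chrom, l.start, l.end) for l in catalog], genes)
            panel = labels.set_index("gene_id")["panel"]
            x = counts[panel == "childhood"].to_numpy()
            y = counts[panel == "control"].to_numpy()
            _, p = comparison.wilcoxon_rank_sum(x, y)
            insignificant += p > 0.05
        assert insignificant >= 9

    def test_planted_density_ratio_separates_medians(self):
        """ratio=2, 200 genes/class: disease median exceeds control median."""
        hits = 0
        fractions = {"adult": 0.0, "childhood": 0.5, "overlap": 0.0, "control": 0.5}
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_genes=400, panel_fractions=fractions,
                            planted_effects={"str_density_ratio": 2.0})
            genes, _, labels = simulate.gen_annotation(cfg)
            catalog = simulate.gen_str_catalog(genes, labels, cfg)
            counts = annotation.count_overlaps(
                [(l.chrom, l.start, l.end) for l in catalog], genes)
            panel = labels.set_index("gene_id")["panel"]
            hits += (np.median(counts[panel == "childhood"])
                     > np.median(counts[panel == "control"]))
        assert hits >= 9


class TestExpressionGenerator:
    def test_unknown_gene_in_plan_is_input_error(self):
        cfg = SimConfig(seed=1, n_genes=10)
        with pytest.raises(ValueError, match="unknown genes"):
            simulate.gen_expression(cfg, ["g1", "g2"],
                                    ExpressionPlan(genes=("nope",), tissue="tissue_01",
                                                   fold=5))

    def test_same_seed_gives_identical_matrices(self):
        cfg = SimConfig(seed=9, n_genes=20)
        ids = [f"g{i}" for i in range(20)]
        a = simulate.gen_expression(cfg, ids)
        b = simulate.gen_expression(cfg, ids)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_mm_values_bounded(self):
        cfg = SimConfig(seed=2, n_genes=50)
        _, mm, _ = simulate.gen_expression(cfg, [f"g{i}" for i in range(50)])
        assert mm.to_numpy().min() >= -1 and mm.to_numpy().max() <= 1

    def test_planted_tenfold_fires_five_fold_rule(self):
        """fold=10 at 10 tissues: planted genes flagged >= 95% of the time."""
        flagged = total = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_genes=100, n_tissues=10)
            ids = [f"g{i}" for i in range(100)]
            plan = ExpressionPlan(genes=tuple(ids[:10]), tissue="tissue_03", fold=10)
            expr, _, _ = simulate.gen_expression(cfg, ids, plan)
            flags = expression.tissue_specific_flags(expr, fold=5)
            flagged += int(flags.loc[ids[:10], "tissue_03"].sum())
            total += 10
        assert flagged / total >= 0.95

    def test_null_fold_keeps_false_positives_nominal(self):
        cfg = SimConfig(seed=3, n_genes=200, n_tissues=12)
        ids = [f"g{i}" for i in range(200)]
        expr, _, _ = simulate.gen_expression(cfg, ids)
        flags = expression.tissue_specific_flags(expr, fold=5)
        # with low-variance lognormal background a 5-fold excess is very rare
        assert flags.to_numpy().mean() < 0.01


class TestVariantGenerator:
    def test_zero_rates_give_empty_table(self):
        cfg = SimConfig(seed=1, n_genes=5, n_cases=50, n_controls=100)
        v = simulate.gen_variants(cfg, {"G00001": (0.0, 0.0)})
        assert v.empty

    def test_rate_outside_unit_interval_rejected(self):
        cfg = SimConfig(seed=1)
        with pytest.raises(ValueError, match="outside"):
            simulate.gen_variants(cfg, {"G00001": (1.5, 0.0)})

    def test_same_seed_identical_and_one_variant_per_proband_gene(self):
        cfg = SimConfig(seed=4, n_cases=200, n_controls=400)
        rates = {"G00001": (0.05, 0.01), "G00002": (0.02, 0.02)}
        a = simulate.gen_variants(cfg, rates)
        b = simulate.gen_variants(cfg, rates)
        pd.testing.assert_frame_equal(a, b)
        assert not a.duplicated(subset=["proband_id", "gene_id"]).any()
        assert a["maf"].lt(0.001).all()


class TestSTRGenotypeGenerator:
    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            simulate.gen_str_genotypes([], SimConfig(seed=1))

    def test_alleles_positive_and_deterministic(self, small_sim):
        cfg = small_sim["config"]
        catalog = small_sim["catalog"][:5]
        a = simulate.gen_str_genotypes(catalog, cfg)
        b = simulate.gen_str_genotypes(catalog, cfg)
        pd.testing.assert_frame_equal(a, b)
        assert (a[["allele1", "allele2"]] >= 1).all().all()
        n_ind = cfg.n_cases + cfg.n_controls
        assert len(a) == n_ind * len(catalog)

    def test_controls_never_inflated(self, small_sim):
        cfg = small_sim["config"]
        catalog = small_sim["catalog"][:5]
        gt = simulate.gen_str_genotypes(catalog, cfg)
        null_cfg = SimConfig(**{**{k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
                               "planted_effects": {"tail_inflation_repeats": 0}})
        gt0 = simulate.gen_str_genotypes(catalog, null_cfg)
        ctrl = gt["cohort"] == "control"
        pd.testing.assert_frame_equal(gt[ctrl].reset_index(drop=True),
                                      gt0[ctrl].reset_index(drop=True))

    def test_homozygous_max_allele(self):
        from panelomics.strtail import max_allele
        assert max_allele(7, 7) == 7
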
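# panelomics

Functional-genomic characterization of disease gene panels partitioned by
age of onset.

Diagnostic gene panels for heterogeneous Mendelian disorders — hereditary
ataxia being the motivating case — are conventionally split into
childhood-onset, adult-onset and overlap-onset gene lists, and patients
are screened only against the panel matching their presentation.
`panelomics` implements the analysis machinery for asking whether that
partition is reflected in the genes' functional-genomic properties, and
for testing the clinical consequences in case/control sequencing cohorts:

* **per-gene features** from standard annotation sources: gene length,
  transcript count, unique exon–exon junctions, GC content; short tandem
  repeat (STR) counts from a HipSTR-style catalog split by repeat period
  (2–6 bp) and genic context (coding exon > 5′UTR > 3′UTR > intron,
  resolved over the union of transcripts); eSTR counts and tissue
  breadth; RepeatMasker LINE/L1, SINE/Alu and SVA element counts; and
  CNCR density — the fraction of the gene span covered by the base-level
  union of constrained non-conserved regions;
* **panel comparison**: every feature tested over all six panel pairs,
  Wilcoxon rank-sum for numeric features (exact for n+m ≤ 12, tie- and
  continuity-corrected normal approximation otherwise), chi-squared with
  Yates correction for categorical ones, Benjamini–Hochberg adjustment
  per feature family;
* **expression-weighted cell-type enrichment (EWCE)**: is the mean
  cell-type expression specificity s(g,c) = m(g,c)/Σ_c′ m(g,c′) of a
  gene set higher than in bootstrap gene sets matched on transcript
  length and GC content (joint quantile bins, per-gene replacement,
  10 000 replicates, add-one p = (1 + #{boot ≥ target})/(B + 1))?
* **balanced feature selection**: Pearson |r| > 0.9 pruning, then
  repeated recursive feature elimination — half the disease genes versus
  an equal bootstrap of controls, logistic-model coefficient ranking,
  subset size chosen by cross-validated Cohen's κ under the 1-SE rule —
  keeping features selected in ≥ 80% of 50 repeats, and a 2-D UMAP
  embedding of the genes on those features;
* **rare-variant burden testing**: per-gene 2×2 carrier tables (MAF
  < 0.1% dominant / < 1% recessive; scenarios LoF, pathogenic score
  > 0.8, pathogenic∧CCR, de novo) compared across onset groups — e.g.
  childhood-onset genes in adult-onset cases versus controls — by
  one-sided Fisher's exact test, a ≥ 4-carrier rule, and one BH family
  over all scenarios;
* **STR repeat-size tails**: for naturally-occurring tri–hexanucleotide
  STRs in coding exons or 5′UTRs of panel genes, the mean of the top-1%
  per-individual maximum allele sizes in cases minus controls, per locus
  and pooled by locus class;
* **a synthetic-data generator** that emulates every input — gene models
  with exon/intron/UTR structure, STR catalogs with class-dependent
  density, expression matrices with planted specificity, carrier tables
  with planted odds ratios, STR genotypes with planted tail inflation —
  so each stage is testable against a known ground truth.

## Worked example

The `analysis/` scripts run the whole study on synthetic data (a
400-gene study: 20 adult, 200 childhood, 80 overlap, 100 control genes;
1122 cases and 6658 controls), writing tables under `results/`:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_gene_features.py
python analysis/03_panel_comparison.py
...
python analysis/07_str_tails.py
```

Selected output (seed 20230110):

```
repeat-expansion mechanism 2x2 (8/23 vs 1/213): chi-squared 57.60, p = 3.205e-14
30 disease-vs-control contrasts at adjusted p < 0.05; features: ['cncr_density',
  'n_line_l1', 'n_sine_alu', 'n_strs', 'n_strs_coding_exon', ...]
931 tests passed the 4-proband rule (298 genes); BH family size 931
median OR 6.84 (planted 7.04); 237 genes FDR-significant at 0.05
naturally_occurring / case_adult: mean top-1% case-control difference +2.22 repeat units
```

Reading these: the 2×2 test reproduces the canonical contrast between
repeat-expansion fractions of adult- and childhood-onset panels; the
planted twofold STR density excess is picked up by every STR feature;
the burden test recovers the planted odds ratio of 7.04 from binomial
carrier sampling; and the planted +10 repeat-unit inflation in 1% of
case alleles surfaces as a positive top-1% tail difference.

The same stages are exposed as a CLI
(`panelomics simulate|annotate|exprfeat|compare|ewce|select|embed|burden|strtail|run-all`);
`panelomics run-all --config cfg.yaml --out dir` runs everything end to
end and writes a manifest with per-file sha256 checksums, so re-runs are
verifiable byte-for-byte.

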
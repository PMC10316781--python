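# Methods

This note documents the statistical procedures, parameter defaults,
numerical conventions and known limitations of `panelomics`.  It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Coordinates and formats

Internal coordinates are 0-based half-open everywhere.  GTF is read and
written as 1-based inclusive (the round trip is an identity, tested).
The STR catalog uses the HipSTR-style BED dialect — tab-separated chrom,
start, end, period, reference repeat count, name — read as 0-based start
with *inclusive* end; catalogs with 1-based starts are handled by
`read_str_bed(..., one_based=True)` (CLI flag `--str-bed-one-based`).
STR-dialect conventions vary between tools, which is why the flag exists.

## Per-gene features

* An interval overlapping k genes contributes to each of the k genes;
  STR loci shared between overlapping genes count toward every gene (a
  per-gene density is a property of the gene, not of the locus).  Strand
  is ignored for assignment.
* STR genic context is assigned by precedence coding exon > 5′UTR >
  3′UTR > intron, evaluated over the union of all transcripts; a locus
  overlapping no exonic part of any transcript is intronic.  Exons of a
  transcript without an annotated CDS are treated as coding.
* `n_junctions` counts unique (donor, acceptor) coordinate pairs across
  transcripts, so a junction shared by two transcripts counts once.
* GC content is (G+C)/(A+C+G+T) over the gene span, case-insensitive,
  with ambiguous bases excluded from the denominator; an all-ambiguous
  span yields a missing value.
* CNCR density is |union(segments) ∩ span| / |span|.  It is invariant
  under segment order and under splitting segments into adjacent pieces
  (tested), and lies in [0, 1] by construction.

## Panel comparison

Numeric features use the Wilcoxon rank-sum test.  For n+m ≤ 12 the
p-value is exact: scipy's exact method for tie-free samples, an
in-package enumeration over all C(n+m, n) group assignments otherwise
(so two identical samples give p = 1 exactly).  Larger samples use the
tie-corrected normal approximation with continuity correction.
Categorical features use chi-squared tests; 2×2 tables apply the Yates
continuity correction by default, with the corrected deviation
max(|O−E|−0.5, 0) floored at zero so near-proportional tables cannot
acquire negative deviations.  The continuity default reproduces the
standard worked example of the repeat-expansion mechanism contrast
(8/23 vs 1/213 → p = 3.205×10⁻¹⁴) and matches common statistical
packages; it is switchable (`continuity=False`).  A zero-margin table is
degenerate and returns p = 1 with a warning.  The six pairwise p-values
of one feature form one BH family; a pair where either group has fewer
than two observations is skipped with a logged reason.

## Expression features

The tissue-specificity rule flags expr(g,t) ≥ 5 × mean over *all*
tissues (the focal tissue included).  Read literally this is
unsatisfiable for T ≤ 5 tissues, so the function requires ≥ 6 tissues
and raises a configuration error otherwise — an explicit guard was
preferred over silently reinterpreting the rule.  The module-membership
rule flags mm(g,t) > 0 with mm(g,t) ≥ 3.5 × mean over the *other*
tissues, with negative values floored at 0 before averaging (a fold
change over a negative baseline is undefined).  Whether the original
rule used the mean or the maximum of the other tissues is ambiguous;
mean is the default and `baseline="max"` is available.  Upstream
residualization (batch, age, sex covariates) is out of scope; matrices
are ingested post-residualization.

The specificity matrix divides each gene's mean cell-type expression by
its row sum; rows sum to 1 (±1e−9) and are invariant under uniform
rescaling of a gene's expression.  All-zero rows are dropped and logged.
The per-(gene, cell type) entry is also exposed as the gene-contribution
report, with zero-total genes reported missing.

## EWCE

Bootstrap gene sets are matched on transcript length and GC content by
joint quantile binning (5 bins per covariate by default; bins are built
on ranks so tied covariates still split evenly).  Each replicate
replaces every target gene with a uniform draw, with replacement, from
that gene's joint bin; whether the original method resamples whole sets
or per-gene is not documented, and per-gene replacement is the
implemented choice.  Draws are independent across replicates.  An empty
bin is widened to the nearest non-empty bin by L1 distance on bin codes
(logged); it cannot arise while targets belong to the universe, but the
fallback keeps the sampler total.  With small universes the joint bins
shrink toward the targets themselves and the test loses power by
construction (tested); universes of a few hundred genes or more are the
intended regime.

The p-value is the add-one permutation estimator
p = (1 + #{replicates with mean ≥ target mean})/(n_boot + 1), which is
never zero and calibrates exactly for finite replicates.  The effect
size is (target mean − bootstrap mean)/bootstrap SD, reported missing
when the bootstrap SD is zero.  BH adjustment runs either over the full
cell-type × gene-set grid (default) or within gene set
(`scope="per_gene_set"`), the latter for granular cell-type levels
where only the number of gene sets is accounted for; the scope is
recorded in the output.

Null calibration and power are computed by
`calibration.ewce_null_ks` / `ewce_power`: 200 replicate seeds at 500
bootstraps for the uniformity check and 50 seeds at 1000 bootstraps for
the power check (50 target genes, 2000-gene universe, 12 cell types,
3-fold planted specificity), sizes chosen so the experiments complete
in seconds while leaving the Kolmogorov–Smirnov and detection margins
wide.

## Feature selection

Features correlated above |r| = 0.9 are pruned greedily: constant
columns first (their correlation is undefined), then, while any pair
exceeds the threshold, the member with the larger mean absolute
correlation to the remaining features is dropped, ties broken by
feature name.  No surviving pair exceeds the threshold (asserted).

Each RFE repeat draws 50% of the disease genes without replacement and
an equal-size bootstrap of controls, z-scores the features within the
sample, and shrinks through a powers-of-two size grid (full set, then
2^k … 1), ranking by absolute standardized logistic-regression
coefficient and scoring each candidate size by stratified 5-fold
cross-validated Cohen's κ.  The subset size is chosen by the 1-SE rule:
the smallest size whose mean κ is within one standard error of the
maximum.  The plain κ-maximizing rule is available
(`size_rule="best"`), but under uninformative labels it picks arbitrary
middling sizes driven by κ noise, which lets features spuriously
correlated with the fixed label assignment stabilize across repeats;
the parsimony rule collapses null models to minimal size and restores
the expected null behavior while leaving planted-effect recovery
intact (both verified by simulation in the acceptance suite).
Selection frequency is the fraction of repeats (default 50) whose best
subset contains the feature; features at frequency ≥ 0.8 are retained.
Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from marginal products; when
both label vectors are constant and equal, κ is defined as 1.

The 2-D embedding z-scores the selected features and runs UMAP with a
fixed seed and a single thread (deterministic given the seed, tested);
the neighbor count shrinks with a warning when there are fewer genes
than neighbors.  UMAP internals are treated as plumbing.

## Burden testing

Variants qualify when their MAF is below the mode-of-inheritance
threshold (0.001 dominant, 0.01 recessive; missing MAF excludes the
variant, logged) and the scenario predicate holds: LoF flag; score
> 0.8; score > 0.8 and constrained coding region; or de novo with the
de-novo-evaluable flag (genotyping trios only).  A proband carries a
gene given ≥ 1 passing dominant variant or ≥ 2 passing recessive
alleles (homozygous counting as two).  Segregation filtering is
modeled as an upstream boolean; pedigree logic is out of scope.  For
the de novo scenario the carrier restriction is on the variant row;
denominators default to the full cohort (an optional per-proband
evaluable table can restrict them).

Each test is a one-sided Fisher's exact test — the upper hypergeometric
tail P(X ≥ a) given the table margins — on case/control carrier counts
for one (panel, case group) combination of the design: childhood genes
× adult cases, adult genes × childhood cases, overlap genes × both,
each versus controls.  Tests with fewer than 4 total carriers are
dropped before a single BH correction across all retained tests of all
scenarios; the family size is recorded in the output.  The odds ratio
is the sample cross-product (a·d)/(b·c) with the Haldane–Anscombe 0.5
added to every cell when any cell is zero (the conditional MLE is a
switchable alternative in principle but is infinite on zero-cell
tables).  When *averaging* odds ratios across replicate cohorts — as
the recovery experiment does — the package averages on the log scale
(geometric mean), the convention used when pooling ORs across studies:
the arithmetic mean of ratio estimators is dominated by the heavy right
tail that sparse control counts produce and overstates the planted
effect substantially at single-digit expected counts.

## STR tails

The screen keeps tri- to hexanucleotide loci in coding exons or 5′UTRs
of panel genes; known-pathogenic expansion loci are tagged but kept so
they can be summarized as their own class.  Each individual contributes
its maximum available allele at a locus (individuals missing a genotype
are excluded at that locus only).  Per group the tail is the
⌈q·n⌉ largest maxima (q = 0.01 default); boundary ties are resolved
deterministically by individual id, making tail membership invariant
under input order (tested).  The headline statistic is the difference
in tail means, case − control, per locus; pooled summaries average
per-locus differences within {known pathogenic, naturally occurring} ×
case group.  Whether "top 1%" is per-locus or pooled across loci is
ambiguous; per-locus is the default and `TailConfig(pooled=True)` pools
the maxima across loci before taking the tail.  No hypothesis test is
attached by default — the quantity is a descriptive trend — but a
label-permutation test (10 000 permutations) is available for synthetic
validation.  Groups below 100 individuals at a locus are skipped with a
reason.

## Synthetic data

All generators derive from one root seed via named
`SeedSequence(seed, spawn_key=...)` streams (one per stage, documented
in `panelomics._rng`), so identical configs give byte-identical outputs
and each stage is independently reproducible.  Defaults emulate the
study conditions: panel fractions 5/50/20/25% (adult, childhood,
overlap, control), 1122 cases (73% adult-onset) versus 6658 controls, a
twofold STR density excess in disease-class genes, qualifying-variant
carrier rates of 6/816 (cases) versus 7/6658 (controls, true OR 7.04),
and +10 repeat units added to 1% of case STR alleles.

Genes are placed non-overlapping on one synthetic chromosome (an option
plants overlapping genes to exercise multi-gene STR assignment), with
lognormal lengths around 3 kb, Poisson transcript counts (mean 3),
exons cut uniformly within the span, and CDS/UTRs assigned
strand-aware from exonic coordinates.  Sequence is emitted with the
exact per-gene GC count for a uniform(0.35, 0.6) target, so realized GC
matches the target to within rounding.  STR counts per gene are Poisson
with intensity proportional to gene length (2 per kb baseline) times
the class ratio; reference repeat counts follow a shifted geometric.
Planted expression specificity sets the target column to fold × the
gene's background mean times a lognormal(0, 0.05) jitter, so the
realized fold matches the requested one.  Carriers are drawn
binomially with at most one qualifying variant per proband per gene
(matching the downstream 2×2 counting); emitted rows pass the dominant
rarity filter and carry high scores plus LoF/CCR/de-novo flags.  STR
alleles are the catalog reference plus a centered, discretized
negative-binomial jitter floored at one repeat — right-skewed like
empirical allele distributions, but a stand-in: the real cohorts'
allele-size distribution is not publicly documented, so absolute tail
sizes from the generator are not meaningful, only planted case/control
contrasts.

What the generator does not emulate: read-level noise and genotyping
error, linkage disequilibrium and population structure, batch effects
in expression, pedigree structure, and correlated features beyond the
geometry the planted effects induce.  Passing tests therefore
demonstrate that the statistical machinery recovers known effects at
realistic sample sizes and stays calibrated under the null — not that
it is robust to the artifacts of real sequencing data.

## Problem sizes in the validation experiments

Exact-test oracles: Fisher against full hypergeometric enumeration on
all small tables plus 2000 random tables with margins up to 30;
Wilcoxon's exact branch against full permutation enumeration for 100
random tie-free samples with n+m ≤ 10; BH against the step-up formula
on 1000 random vectors; interval features against per-base scans on 200
random instances.  Recovery/calibration experiments: burden OR over 500
simulated cohorts plus a 100-gene null; EWCE as above; RFE over 20
planted and 20 permuted-label datasets at 50 repeats each; STR tails
over 50 planted and 20 null seeds at 500 cases / 2000 controls and 40
loci.  These sizes keep the full validation run within a few minutes on
one CPU while leaving clear margins to every threshold.
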
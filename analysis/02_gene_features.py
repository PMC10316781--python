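#!/usr/bin/env python
"""Compute the per-gene feature table.

Reads the simulated annotation (GTF, FASTA, STR catalog, RepeatMasker
table, CNCR intervals), assigns each STR its genic context by the
coding > 5'UTR > 3'UTR > intron precedence rule, and writes the
genes x features table with its metadata sidecar to
results/features.tsv.
"""

from pathlib import Path

import pandas as pd

from panelomics import annotation

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    inputs = ROOT / "inputs"
    genes = annotation.read_gtf(inputs / "genes.gtf")
    genome = annotation.read_fasta(inputs / "genome.fasta")
    catalog = annotation.annotate_catalog(
        annotation.read_str_bed(inputs / "str_catalog.bed"), genes)
    elements = annotation.read_rmsk(inputs / "rmsk.tsv")
    cncr = annotation.read_bed3(inputs / "cncr.bed")

    table = annotation.build_feature_table(genes, catalog, None, elements,
                                           cncr, genome)
    annotation.write_feature_table(table, ROOT / "features.tsv")

    ctx = pd.Series([l.context for l in catalog]).value_counts()
    print(f"features: {table.shape[0]} genes x {table.shape[1]} columns")
    print(f"STR catalog: {len(catalog)} loci; contexts: {ctx.to_dict()}")
    print(f"median STRs per gene: {table['n_strs'].median():.1f}")


if __name__ == "__main__":
    main()
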
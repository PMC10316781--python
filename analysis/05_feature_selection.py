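#!/usr/bin/env python
"""Prune redundant features, select stable ones, and embed the genes.

Removes features correlated above |r| = 0.9, runs the class-balanced
recursive feature elimination (50 repeats of half the disease genes vs
an equal bootstrap of controls, subset size by cross-validated Cohen's
kappa), keeps features selected in at least 80% of repeats, and embeds
the genes in 2-D with UMAP on the retained features.
"""

from pathlib import Path

import pandas as pd

from panelomics import selection

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20230110


def main() -> None:
    feats = pd.read_csv(ROOT / "features.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(ROOT / "inputs" / "labels.tsv", sep="\t")
    binary = labels.set_index("gene_id")["panel"].map(
        lambda p: "control" if p == "control" else "disease")

    numeric = feats.select_dtypes("number")
    cfg = selection.RFEConfig(repeats=50, seed=SEED)
    kept, pruned = selection.prune_correlated(numeric, cfg.corr_threshold)
    print(f"correlation pruning: kept {len(kept)}, removed {len(pruned)} "
          f"({sorted(pruned)})")

    report = selection.balanced_rfe(numeric[kept], binary.loc[numeric.index], cfg)
    out = report.frequencies.rename("selection_frequency").to_frame()
    out["retained"] = out.index.isin(report.retained)
    out.sort_values("selection_frequency", ascending=False).to_csv(
        ROOT / "selection.tsv", sep="\t", index_label="feature")
    print(f"retained at frequency >= {cfg.keep_frequency}: {report.retained}")

    cols = report.retained or kept
    coords = selection.embed_2d(numeric[cols], seed=SEED)
    coords = coords.join(labels.set_index("gene_id")["panel"])
    coords.to_csv(ROOT / "embedding.tsv", sep="\t", index_label="gene_id")
    print(f"embedded {len(coords)} genes on {len(cols)} features "
          f"-> {ROOT / 'embedding.tsv'}")


if __name__ == "__main__":
    main()
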
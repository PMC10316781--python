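#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds a 400-gene study in the proportions of the real panels (5% adult-,
50% childhood-, 20% overlap-onset, 25% control genes) with the default
planted effects: a twofold STR density excess in disease-class genes,
carrier rates of 6/816 vs 7/6658 for qualifying variants, and a +10
repeat-unit inflation in 1% of case STR alleles.  Writes GTF, FASTA, the
HipSTR-style STR catalog, expression matrices, cohort table and a
checksummed manifest under results/inputs/.
"""

from pathlib import Path

from panelomics import simulate
from panelomics.cli import write_manifest, write_simulated_inputs

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 20230110


def main() -> None:
    cfg = simulate.SimConfig(seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    files = write_simulated_inputs(cfg, OUT)
    write_manifest(cfg, OUT, files, stage="simulate")
    counts = simulate.panel_counts(cfg)
    print(f"wrote {len(files)} input files to {OUT}")
    print("genes per panel:", counts)
    print(f"cohorts: {cfg.n_cases} cases ({cfg.case_adult_fraction:.0%} adult), "
          f"{cfg.n_controls} controls")


if __name__ == "__main__":
    main()
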
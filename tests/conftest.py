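import pandas as pd
import pytest

from panelomics import annotation, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(seed=7, n_genes=60, n_cases=120, n_controls=480)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """One small simulated study shared across read-only tests."""
    genes, genome, labels = simulate.gen_annotation(small_config)
    catalog = simulate.gen_str_catalog(genes, labels, small_config)
    catalog = annotation.annotate_catalog(catalog, genes)
    return {"config": small_config, "genes": genes, "genome": genome,
            "labels": labels, "catalog": catalog}


@pytest.fixture
def toy_gene():
    """Two-transcript gene with known exon/CDS/UTR structure (+ strand).

    T1: exons [100,200) and [300,400); 5'UTR [100,150), CDS [150,200)+[300,350),
    3'UTR [350,400).  T2: single exon [100,400) fully annotated the same way.
    """
    t1 = annotation.Transcript(
        "T1", exons=[(100, 200), (300, 400)],
        cds=[(150, 200), (300, 350)], utr5=[(100, 150)], utr3=[(350, 400)],
    )
    t2 = annotation.Transcript(
        "T2", exons=[(100, 400)],
        cds=[(150, 350)], utr5=[(100, 150)], utr3=[(350, 400)],
    )
    return annotation.GeneModel("GX", "chr1", 100, 400, "+", [t1, t2])


@pytest.fixture
def estr_table():
    return pd.DataFrame({
        "locus_id": ["L1", "L2", "L2", "L3"],
        "gene_id": ["GA", "GA", "GA", "GB"],
        "tissues": ["brain", "brain,blood", "brain,blood", "muscle"],
    })
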
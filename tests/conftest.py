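import logging

import numpy as np
import pandas as pd
import pytest

from cytobalance.annotations import AnnotationSet, GeneRecord
from cytobalance.quantify import CountTable, SampleMeta
from cytobalance.synthetic_data import paper_calibrated, simulate_experiment

logging.getLogger("cytobalance").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def preset_params():
    return paper_calibrated()


@pytest.fixture(scope="session")
def small_params(preset_params):
    """Scaled-down preset for fast unit tests."""
    return preset_params.replace(
        n_nuclear_genes=400,
        n_plastid_genes=30,
        n_mito_genes=20,
        n_spike_species=30,
        depth=300_000,
    )


@pytest.fixture(scope="session")
def preset_sim(preset_params):
    """One full paper-calibrated simulation at the preset seed."""
    return simulate_experiment(preset_params)


@pytest.fixture
def toy_annotation():
    """20-gene annotation covering every genome, class and tier."""
    recs = {}

    def add(gid, genome, length, targeting="unknown", tier="none", cpx=None):
        recs[gid] = GeneRecord(gid, genome, length, targeting, tier, cpx)

    add("AT1G00010", "nuclear", 1.0, "plastid", "direct", "CPX1")
    add("AT1G00020", "nuclear", 2.0, "plastid", "complexed", "CPX1")
    add("AT1G00030", "nuclear", 0.5, "plastid", "none")
    add("AT2G00010", "nuclear", 1.0, "mitochondrion", "direct", "CPX2")
    add("AT2G00020", "nuclear", 1.5, "mitochondrion", "none")
    add("AT3G00010", "nuclear", 1.0, "dual", "complexed")
    add("AT3G00020", "nuclear", 2.5, "other")
    add("AT4G00010", "nuclear", 1.0, "other")
    add("AT4G00020", "nuclear", 0.8, "unknown")
    add("AT5G00010", "nuclear", 1.2, "unknown")
    add("AT5G00020", "nuclear", 1.0, "other")
    add("ATCG00010", "plastid", 1.5, "not_applicable", "none", "CPX1")
    add("ATCG00020", "plastid", 1.0, "not_applicable")
    add("ATCG00030", "plastid", 0.5, "not_applicable")
    add("ATMG00010", "mitochondrion", 2.0, "not_applicable", "none", "CPX2")
    add("ATMG00020", "mitochondrion", 3.0, "not_applicable")
    add("ERCC-00001", "spike", 0.5, "not_applicable")
    add("ERCC-00002", "spike", 1.0, "not_applicable")
    add("ERCC-00003", "spike", 0.25, "not_applicable")
    add("AT1G00040", "nuclear", 1.0, "plastid", "direct", "CPX1")
    return AnnotationSet(records=recs)


@pytest.fixture
def toy_counts(toy_annotation):
    """Deterministic 20-gene x 4-sample count table (2 ploidies x 2 reps)."""
    genes = toy_annotation.gene_ids()
    rng = np.random.default_rng(99)
    data = rng.integers(1, 500, size=(len(genes), 4))
    df = pd.DataFrame(
        data, index=genes, columns=["s2a", "s2b", "s4a", "s4b"], dtype=np.int64
    )
    return CountTable(counts=df)


@pytest.fixture
def toy_meta():
    return [
        SampleMeta("s2a", "leaf", "2C", 1, rna_per_dna=10.0),
        SampleMeta("s2b", "leaf", "2C", 2, rna_per_dna=10.0),
        SampleMeta("s4a", "leaf", "4C", 1, rna_per_dna=9.5),
        SampleMeta("s4b", "leaf", "4C", 2, rna_per_dna=9.5),
    ]
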
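"""ERCC spike-in based absolute dosage normalization.

The spiking strategy adds exogenous RNA to each sample in proportion to the
genomic DNA associated with that sample's RNA in the tissue, so spike read
totals act as a per-genome-copy anchor: dividing plant read counts by spike
read counts yields expression per unit of DNA, i.e. per gene copy, in units
that are arbitrary but comparable across samples of one experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cytobalance.annotations import AnnotationSet
from cytobalance.quantify import (
    CountTable,
    ExpressionTable,
    SampleMeta,
    mean_expression,
    tpm_ratio,
)


@dataclass(frozen=True)
class SpikeDesign:
    """Spike-in dosing record for one library."""

    sample_id: str
    rna_mass: float
    rna_per_dna: float
    spike_mass: float

    def __post_init__(self) -> None:
        for name in ("rna_mass", "rna_per_dna", "spike_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.sample_id}: {name} must be > 0")


def transcriptome_size(rna_yield: float, dna_yield: float) -> float:
    """Total RNA per unit of co-extracted DNA (the transcriptome-size proxy)."""
    if rna_yield <= 0 or dna_yield <= 0:
        raise ValueError("yields must be positive")
    return rna_yield / dna_yield


def spike_mass_for(rna_mass: float, rna_per_dna: float, k: float = 1.0) -> float:
    """Spike mass proportional to the DNA underlying a given RNA mass.

    spike_mass = k * rna_mass / rna_per_dna, so a tissue with more DNA per
    unit RNA (smaller transcriptome) receives proportionally more spike.
    """
    if rna_mass <= 0 or rna_per_dna <= 0 or k <= 0:
        raise ValueError("rna_mass, rna_per_dna and k must all be positive")
    return k * rna_mass / rna_per_dna


def check_spike_design(designs: Sequence[SpikeDesign], rtol: float = 1e-6) -> float:
    """Verify proportional spiking across an experiment; returns the shared k.

    Every design must satisfy spike_mass = k * rna_mass / rna_per_dna for one
    common constant k.
    """
    if not designs:
        raise ValueError("no spike designs")
    ks = np.array([d.spike_mass * d.rna_per_dna / d.rna_mass for d in designs])
    if not np.allclose(ks, ks[0], rtol=rtol):
        raise ValueError(f"spike masses are not proportional to DNA: k values {ks.tolist()}")
    return float(ks[0])


def read_spike_design_tsv(path: str | Path) -> list[SpikeDesign]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return [
        SpikeDesign(
            sample_id=r.sample_id,
            rna_mass=float(r.rna_mass),
            rna_per_dna=float(r.rna_per_dna),
            spike_mass=float(r.spike_mass),
        )
        for r in df.itertuples(index=False)
    ]


def write_spike_design_tsv(designs: Sequence[SpikeDesign], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "rna_mass": repr(d.rna_mass),
                "rna_per_dna": repr(d.rna_per_dna),
                "spike_mass": repr(d.spike_mass),
            }
            for d in designs
        ]
    ).to_csv(path, sep="\t", index=False)


def per_genome_expression(
    counts: CountTable, lengths_kb: Mapping[str, float] | pd.Series
) -> ExpressionTable:
    """Scale plant RPK values by each sample's total spike reads.

    value_{g,s} = RPK_{g,s} / (sum of spike counts in s) * 1e6. Gene-length
    correction mirrors TPM so per-genome and TPM ratios are comparable per
    gene; the 1e6 factor is cosmetic (all downstream use is ratio-based).
    """
    lengths = pd.Series(lengths_kb, dtype=float).reindex(counts.genes)
    plant = counts.plant()
    if lengths.loc[plant.index].isna().any():
        missing = lengths.loc[plant.index][lengths.loc[plant.index].isna()].index[:5]
        raise ValueError(f"no length for genes: {list(missing)}")
    spike_totals = counts.spikes().sum(axis=0)
    dead = spike_totals[spike_totals <= 0]
    if len(dead):
        raise ValueError(f"samples with zero spike reads: {list(dead.index)}")
    rpk = plant.div(lengths.loc[plant.index], axis=0)
    values = rpk.div(spike_totals, axis=1) * 1e6
    return ExpressionTable(
        values=values,
        basis="per_genome",
        spike_flags=pd.Series(False, index=values.index),
    )


def per_genome_ratio(
    expr: ExpressionTable,
    meta: Sequence[SampleMeta],
    annotations: AnnotationSet,
    organ: str,
    ploidy_num: str,
    ploidy_den: str,
    min_mean: float = 0.0,
) -> pd.DataFrame:
    """Per-gene ratios of replicate-mean per-genome expression, with classes.

    Same contract as :func:`cytobalance.quantify.tpm_ratio`: zero-mean genes
    are excluded, and each row carries the gene's genome/targeting/tier.
    """
    if expr.basis != "per_genome":
        raise ValueError(f"expected per_genome expression, got basis={expr.basis!r}")
    mean_num = mean_expression(expr, meta, organ, ploidy_num)
    mean_den = mean_expression(expr, meta, organ, ploidy_den)
    return tpm_ratio(mean_num, mean_den, annotations, min_mean=min_mean)
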
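"""Count tables, TPM normalization, replicate means and ploidy-ratio distributions.

TPM follows the reads-per-kilobase convention: per gene, RPK = count / length
in kb; per sample, TPM = RPK / (sum of RPK / 1e6). Spike-in rows are carried
through with TPM computed against the same denominator but are excluded from
the denominator sum, so plant TPMs stay comparable across samples with
different spike fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cytobalance.annotations import AnnotationSet, classify_genome

logger = logging.getLogger(__name__)

PLOIDIES = ("2C", "4C", "8C")
ORGANS = ("sepal", "leaf")


@dataclass(frozen=True)
class SampleMeta:
    """Descriptor for one RNA-seq library."""

    sample_id: str
    organ: str
    ploidy: str
    replicate: int
    rna_per_dna: float | None = None
    spike_mix: str | None = None

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"{self.sample_id}: unknown organ {self.organ!r}")
        if self.ploidy not in PLOIDIES:
            raise ValueError(f"{self.sample_id}: unknown ploidy {self.ploidy!r}")
        if self.replicate < 1:
            raise ValueError(f"{self.sample_id}: replicate must be positive")
        if self.rna_per_dna is not None and self.rna_per_dna <= 0:
            raise ValueError(f"{self.sample_id}: rna_per_dna must be > 0")

    @property
    def cytotype(self) -> tuple[str, str]:
        return (self.organ, self.ploidy)


def check_meta(meta: Sequence[SampleMeta]) -> None:
    keys = [(m.organ, m.ploidy, m.replicate) for m in meta]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (organ, ploidy, replicate) in sample metadata")
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample metadata")


def samples_for(meta: Sequence[SampleMeta], organ: str, ploidy: str) -> list[str]:
    """Sample ids of one cytotype, ordered by replicate index."""
    chosen = sorted(
        (m for m in meta if m.organ == organ and m.ploidy == ploidy),
        key=lambda m: m.replicate,
    )
    return [m.sample_id for m in chosen]


def read_meta_tsv(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        rpd = getattr(row, "rna_per_dna", "")
        mix = getattr(row, "spike_mix", "")
        out.append(
            SampleMeta(
                sample_id=row.sample_id,
                organ=row.organ,
                ploidy=row.ploidy,
                replicate=int(row.replicate),
                rna_per_dna=float(rpd) if rpd not in ("", "NA") else None,
                spike_mix=mix or None,
            )
        )
    check_meta(out)
    return out


def write_meta_tsv(meta: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "organ": m.organ,
            "ploidy": m.ploidy,
            "replicate": m.replicate,
            "rna_per_dna": "" if m.rna_per_dna is None else repr(m.rna_per_dna),
            "spike_mix": m.spike_mix or "",
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class CountTable:
    """Nonnegative integer gene x sample matrix with spike rows flagged."""

    counts: pd.DataFrame  # genes x samples, integer
    spike_flags: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts.index.name = "gene_id"
        if self.spike_flags is None:
            self.spike_flags = pd.Series(
                [classify_genome(g) == "spike" for g in self.counts.index],
                index=self.counts.index,
            )
        else:
            self.spike_flags = self.spike_flags.reindex(self.counts.index)
            if self.spike_flags.isna().any():
                raise ValueError("spike_flags missing entries for some genes")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def plant(self) -> pd.DataFrame:
        """Counts restricted to non-spike genes."""
        return self.counts.loc[~self.spike_flags]

    def spikes(self) -> pd.DataFrame:
        return self.counts.loc[self.spike_flags.astype(bool)]

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_matrix_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls._from_frame(df)

    @classmethod
    def from_htseq_files(cls, paths: Mapping[str, str | Path]) -> "CountTable":
        """Merge per-sample 2-column HTSeq-count files: {sample_id: path}."""
        columns = {}
        for sample_id, p in paths.items():
            col = pd.read_csv(
                p, sep="\t", header=None, names=["gene_id", sample_id], index_col=0
            )[sample_id]
            columns[sample_id] = col
        df = pd.DataFrame(columns)
        if df.isna().any().any():
            raise ValueError("HTSeq files do not share an identical gene universe")
        return cls._from_frame(df)

    @classmethod
    def _from_frame(cls, df: pd.DataFrame) -> "CountTable":
        special = df.index.astype(str).str.startswith("__")
        if special.any():
            dropped = df.loc[special]
            logger.info(
                "dropping %d HTSeq special counter rows (total reads: %s)",
                int(special.sum()),
                dropped.sum(axis=0).to_dict(),
            )
            df = df.loc[~special]
        return cls(counts=df.astype(np.int64))


@dataclass
class ExpressionTable:
    """Gene x sample expression values on a declared basis (tpm | per_genome)."""

    values: pd.DataFrame
    basis: str = "tpm"
    spike_flags: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.basis not in ("tpm", "per_genome"):
            raise ValueError(f"unknown basis {self.basis!r}")
        self.values.index.name = "gene_id"
        if self.spike_flags is None:
            self.spike_flags = pd.Series(
                [classify_genome(g) == "spike" for g in self.values.index],
                index=self.values.index,
            )
        if self.basis == "tpm":
            plant_sums = self.values.loc[~self.spike_flags].sum(axis=0)
            if not np.allclose(plant_sums, 1e6, rtol=1e-6):
                raise ValueError(
                    f"TPM columns do not sum to 1e6: {plant_sums.to_dict()}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# basis={self.basis}\n")
            out = self.values.copy()
            out.index.name = "gene_id"
            out.to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionTable":
        with open(path) as fh:
            header = fh.readline().strip()
            basis = "tpm"
            if header.startswith("# basis="):
                basis = header.split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(values=df, basis=basis)


def compute_tpm(counts: CountTable, lengths_kb: Mapping[str, float] | pd.Series) -> ExpressionTable:
    """Normalize a count table to transcripts per million.

    Per sample: RPK_g = count_g / length_kb_g; TPM_g = RPK_g / (sum RPK / 1e6),
    where the sum runs over non-spike genes only. Spike rows receive TPM
    values against the same denominator.
    """
    lengths = pd.Series(lengths_kb, dtype=float)
    missing = [g for g in counts.genes if g not in lengths.index or not np.isfinite(lengths.get(g, np.nan))]
    if missing:
        raise ValueError(f"no length for genes: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    lens = lengths.reindex(counts.genes)
    if (lens <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpk = counts.counts.div(lens, axis=0)
    plant_rpk_sum = rpk.loc[~counts.spike_flags].sum(axis=0)
    dead = plant_rpk_sum[plant_rpk_sum <= 0]
    if len(dead):
        raise ValueError(f"samples with zero non-spike counts: {list(dead.index)}")
    tpm = rpk.div(plant_rpk_sum / 1e6, axis=1)
    return ExpressionTable(values=tpm, basis="tpm", spike_flags=counts.spike_flags.copy())


def mean_expression(
    expr: ExpressionTable,
    meta: Sequence[SampleMeta],
    organ: str,
    ploidy: str,
) -> pd.Series:
    """Per-gene arithmetic mean expression across a cytotype's replicates."""
    ids = samples_for(meta, organ, ploidy)
    if not ids:
        raise ValueError(f"no samples for cytotype ({organ}, {ploidy})")
    missing = [s for s in ids if s not in expr.values.columns]
    if missing:
        raise ValueError(f"samples in metadata but not expression table: {missing}")
    return expr.values[ids].mean(axis=1)


def cytotype_means(expr: ExpressionTable, meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Replicate-mean expression for every cytotype present in the metadata.

    Columns are a MultiIndex of (organ, ploidy).
    """
    cytotypes = sorted({m.cytotype for m in meta})
    cols = {ct: mean_expression(expr, meta, *ct) for ct in cytotypes}
    return pd.DataFrame(cols)


def tpm_ratio(
    mean_a: pd.Series,
    mean_b: pd.Series,
    annotations: AnnotationSet | None = None,
    min_mean: float = 0.0,
) -> pd.DataFrame:
    """Per-gene expression ratios mean_a / mean_b with class labels attached.

    Genes are kept only when both means exceed ``min_mean`` (strictly), so
    zero-expression genes are excluded by default and every returned ratio is
    positive and finite.

    Returns a DataFrame indexed by gene_id with columns
    ``ratio, genome, targeting, tier`` (class columns empty if no
    annotations are given).
    """
    shared = mean_a.index.intersection(mean_b.index)
    a = mean_a.reindex(shared)
    b = mean_b.reindex(shared)
    keep = (a > min_mean) & (b > min_mean)
    ratio = (a[keep] / b[keep]).rename("ratio")
    df = ratio.to_frame()
    if annotations is not None:
        df["genome"] = [annotations[g].genome if g in annotations else "" for g in df.index]
        df["targeting"] = [annotations[g].targeting if g in annotations else "" for g in df.index]
        df["tier"] = [annotations[g].interaction_tier if g in annotations else "" for g in df.index]
    else:
        df["genome"] = ""
        df["targeting"] = ""
        df["tier"] = ""
    df.index.name = "gene_id"
    return df
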
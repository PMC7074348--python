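"""Gene annotations: genome-of-origin, exon-union lengths, organelle targeting.

Genome-of-origin follows TAIR locus nomenclature (``AT1G``--``AT5G`` nuclear,
``ATCG`` plastid, ``ATMG`` mitochondrion, ``ERCC-`` spike-in), with a fallback
to the GFF3 chromosome (``ChrC``/``ChrM``) when the prefix is unrecognized.
Targeting classes and interaction tiers follow the curated
targeting-database convention: nuclear genes are classed by the compartment
their product is targeted to, and organelle-targeted genes are further
tiered by whether they participate in complexes with organelle-encoded
molecules (``complexed``) or physically contact organelle-encoded proteins
(``direct``, a subset of ``complexed``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

GENOMES = ("nuclear", "plastid", "mitochondrion", "spike")
TARGETING_CLASSES = ("plastid", "mitochondrion", "dual", "other", "unknown", "not_applicable")
NUCLEAR_TARGETING_CLASSES = ("plastid", "mitochondrion", "dual", "other", "unknown")
ORGANELLE_TARGETED = ("plastid", "mitochondrion", "dual")
TIERS = ("none", "complexed", "direct")

_NUCLEAR_RE = re.compile(r"^AT[1-5]G", re.IGNORECASE)
_CHROM_GENOME = {"chrc": "plastid", "chrm": "mitochondrion"}


def classify_genome(gene_id: str, chromosome: str | None = None) -> str:
    """Classify a locus identifier into its genome of origin.

    Parameters
    ----------
    gene_id
        Locus identifier (AGI-style or ERCC spike name). Case-insensitive.
    chromosome
        Optional chromosome name used as a fallback when the identifier
        prefix is unrecognized (``ChrC`` -> plastid, ``ChrM`` -> mitochondrion).

    Returns
    -------
    str
        One of ``nuclear``, ``plastid``, ``mitochondrion``, ``spike``.
    """
    if not gene_id:
        raise ValueError("gene_id must be non-empty")
    gid = gene_id.upper()
    if gid.startswith("ATCG"):
        return "plastid"
    if gid.startswith("ATMG"):
        return "mitochondrion"
    if _NUCLEAR_RE.match(gid):
        return "nuclear"
    if gid.startswith("ERCC-"):
        return "spike"
    if chromosome is not None:
        fallback = _CHROM_GENOME.get(chromosome.lower())
        if fallback is not None:
            return fallback
    logger.warning("unrecognized gene id prefix for %r; classifying as nuclear", gene_id)
    return "nuclear"


@dataclass
class GeneRecord:
    """One gene's genome of origin, length and targeting classification."""

    gene_id: str
    genome: str
    length_kb: float
    targeting: str = "unknown"
    interaction_tier: str = "none"
    complex_id: str | None = None

    def __post_init__(self) -> None:
        if self.genome not in GENOMES:
            raise ValueError(f"{self.gene_id}: unknown genome {self.genome!r}")
        if self.length_kb <= 0:
            raise ValueError(f"{self.gene_id}: length_kb must be > 0, got {self.length_kb}")
        if self.targeting not in TARGETING_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown targeting class {self.targeting!r}")
        if self.interaction_tier not in TIERS:
            raise ValueError(f"{self.gene_id}: unknown interaction tier {self.interaction_tier!r}")
        if self.genome == "spike":
            if self.targeting != "not_applicable" or self.interaction_tier != "none":
                raise ValueError(f"{self.gene_id}: spike genes carry no targeting annotation")
        elif self.genome in ("plastid", "mitochondrion"):
            if self.targeting != "not_applicable":
                raise ValueError(
                    f"{self.gene_id}: organelle-encoded genes have targeting=not_applicable"
                )
        else:  # nuclear
            if self.targeting == "not_applicable":
                raise ValueError(f"{self.gene_id}: nuclear genes need a real targeting class")
            if self.interaction_tier != "none" and self.targeting not in ORGANELLE_TARGETED:
                raise ValueError(
                    f"{self.gene_id}: tier {self.interaction_tier!r} requires organelle "
                    f"targeting, got {self.targeting!r}"
                )

    @property
    def is_organelle_targeted(self) -> bool:
        return self.genome == "nuclear" and self.targeting in ORGANELLE_TARGETED


@dataclass
class AnnotationSet:
    """Collection of :class:`GeneRecord` keyed by gene id."""

    records: dict[str, GeneRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, rec in self.records.items():
            if gid != rec.gene_id:
                raise ValueError(f"key {gid!r} does not match record id {rec.gene_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.records[gene_id]

    def get(self, gene_id: str) -> GeneRecord | None:
        return self.records.get(gene_id)

    def gene_ids(self) -> list[str]:
        return list(self.records)

    def lengths_kb(self) -> pd.Series:
        return pd.Series({g: r.length_kb for g, r in self.records.items()}, name="length_kb")

    def genome_of(self) -> pd.Series:
        return pd.Series({g: r.genome for g, r in self.records.items()}, name="genome")

    def targeting_of(self) -> pd.Series:
        return pd.Series({g: r.targeting for g, r in self.records.items()}, name="targeting")

    def tier_of(self) -> pd.Series:
        return pd.Series({g: r.interaction_tier for g, r in self.records.items()}, name="tier")

    def genes_by_genome(self, genome: str) -> list[str]:
        return [g for g, r in self.records.items() if r.genome == genome]

    def genes_by_targeting(self, targeting: str) -> list[str]:
        return [g for g, r in self.records.items() if r.targeting == targeting]

    def complex_members(self, complex_id: str) -> list[str]:
        return [g for g, r in self.records.items() if r.complex_id == complex_id]

    def unclassified(self, gene_ids: Iterable[str]) -> list[str]:
        """Gene ids from a count table that do not resolve here."""
        return [g for g in gene_ids if g not in self.records]

    def class_counts(self) -> dict[str, dict[str, int]]:
        genome = self.genome_of().value_counts().to_dict()
        targeting = self.targeting_of().value_counts().to_dict()
        tier = self.tier_of().value_counts().to_dict()
        return {"genome": genome, "targeting": targeting, "tier": tier}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": r.gene_id,
                "genome": r.genome,
                "length_kb": r.length_kb,
                "targeting": r.targeting,
                "tier": r.interaction_tier,
                "complex": "" if r.complex_id is None else r.complex_id,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "genome", "length_kb", "targeting", "tier", "complex"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AnnotationSet":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "complex": str}, keep_default_na=False)
        records = {}
        for row in df.itertuples(index=False):
            complex_id = row.complex if row.complex else None
            records[row.gene_id] = GeneRecord(
                gene_id=row.gene_id,
                genome=row.genome,
                length_kb=float(row.length_kb),
                targeting=row.targeting,
                interaction_tier=row.tier,
                complex_id=complex_id,
            )
        return cls(records=records, provenance={"source": str(path)})

    @classmethod
    def build(
        cls,
        lengths: Mapping[str, float],
        chromosomes: Mapping[str, str] | None = None,
        targeting: Mapping[str, tuple[str, str, str | None]] | None = None,
        provenance: dict | None = None,
    ) -> "AnnotationSet":
        """Assemble an AnnotationSet from length, chromosome and targeting maps.

        ``targeting`` maps gene_id -> (targeting, tier, complex_id) and is only
        applied to nuclear genes; unlisted nuclear genes default to
        ``(unknown, none, None)``.
        """
        chromosomes = chromosomes or {}
        targeting = targeting or {}
        records = {}
        for gid, length_kb in lengths.items():
            genome = classify_genome(gid, chromosomes.get(gid))
            if genome == "nuclear":
                tgt, tier, cpx = targeting.get(gid, ("unknown", "none", None))
            elif genome == "spike":
                tgt, tier, cpx = "not_applicable", "none", None
            else:
                tgt, tier, cpx = "not_applicable", "none", targeting.get(gid, (None, None, None))[2]
            records[gid] = GeneRecord(
                gene_id=gid,
                genome=genome,
                length_kb=length_kb,
                targeting=tgt,
                interaction_tier=tier,
                complex_id=cpx,
            )
        return cls(records=records, provenance=provenance or {})


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total covered length of 0-based half-open intervals."""
    total = 0
    end = -1
    for start, stop in sorted(intervals):
        if start > end:
            total += stop - start
            end = stop
        elif stop > end:
            total += stop - end
            end = stop
    return total


def _gff3_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key] = value
    return out


def load_gff3(path: str | Path) -> tuple[dict[str, float], dict[str, str]]:
    """Parse a GFF3 gene annotation into exon-union lengths and chromosomes.

    Expects the common gene/mRNA/exon feature hierarchy with ``ID``/``Parent``
    attributes. Gene length is the union of all exon intervals across all
    isoforms, in kilobases. Genes without exon features fall back to the gene
    span with a warning. GFF3 coordinates are 1-based inclusive; they are
    converted to 0-based half-open internally.

    Returns
    -------
    (lengths_kb, chromosomes)
        Two dicts keyed by gene id.
    """
    gene_span: dict[str, tuple[int, int]] = {}
    gene_chrom: dict[str, str] = {}
    mrna_gene: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    pending_exons: list[tuple[str, int, int]] = []  # exon rows seen before their mRNA

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: expected 9 fields")
            chrom, _source, ftype, start_s, end_s, _score, _strand, _phase, attrs = fields
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed coordinates on line {lineno}") from exc
            if start < 1 or end < start:
                raise ValueError(f"{path}: invalid interval on line {lineno}: {start}-{end}")
            # to 0-based half-open
            iv = (start - 1, end)
            attr = _gff3_attributes(attrs)
            if ftype == "gene":
                gid = _strip_version(attr.get("ID", ""))
                if not gid:
                    raise ValueError(f"{path}: gene without ID on line {lineno}")
                gene_span[gid] = iv
                gene_chrom[gid] = chrom
            elif ftype == "mRNA":
                mid = attr.get("ID", "")
                parent = _strip_version(attr.get("Parent", ""))
                if mid and parent:
                    mrna_gene[mid] = parent
            elif ftype == "exon":
                parent = attr.get("Parent", "")
                if not parent:
                    raise ValueError(f"{path}: exon without Parent on line {lineno}")
                for p in parent.split(","):
                    pending_exons.append((p, iv[0], iv[1]))

    for parent, s, e in pending_exons:
        gid = mrna_gene.get(parent, _strip_version(parent))
        exons.setdefault(gid, []).append((s, e))

    lengths_kb: dict[str, float] = {}
    for gid, span in gene_span.items():
        ivs = exons.get(gid)
        if ivs:
            bp = _union_length(ivs)
        else:
            logger.warning("gene %s has no exon features; falling back to gene span", gid)
            bp = span[1] - span[0]
        lengths_kb[gid] = bp / 1000.0
    # exons whose parents never resolved to a known gene become their own genes
    for gid, ivs in exons.items():
        if gid not in lengths_kb:
            lengths_kb[gid] = _union_length(ivs) / 1000.0
    return lengths_kb, gene_chrom


def _strip_version(feature_id: str) -> str:
    """Drop a trailing Araport-style ``.Araport11.447`` / ``.1`` suffix from gene IDs."""
    return feature_id.split(".")[0] if feature_id else feature_id


def load_targeting(path: str | Path) -> dict[str, tuple[str, str, str | None]]:
    """Load a targeting/interaction table (TSV: gene_id, targeting, tier[, complex]).

    Unknown class tokens raise with the offending token and row number.
    Genes absent from the table are left to default to ``(unknown, none, None)``
    at :meth:`AnnotationSet.build` time.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "targeting", "tier"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    has_complex = "complex" in df.columns
    out: dict[str, tuple[str, str, str | None]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tgt = row.targeting.strip()
        tier = row.tier.strip()
        if tgt not in NUCLEAR_TARGETING_CLASSES:
            raise ValueError(f"{path}: row {i}: unknown targeting class {tgt!r}")
        if tier not in TIERS:
            raise ValueError(f"{path}: row {i}: unknown tier {tier!r}")
        if tier != "none" and tgt not in ORGANELLE_TARGETED:
            raise ValueError(
                f"{path}: row {i}: tier {tier!r} requires organelle targeting, got {tgt!r}"
            )
        cpx = getattr(row, "complex", "").strip() if has_complex else ""
        out[row.gene_id.strip()] = (tgt, tier, cpx or None)
    return out
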
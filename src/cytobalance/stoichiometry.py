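"""Compartment-level stoichiometry: targeted fractions, organelle/nuclear
bulk ratios, balance ratios, per-genome ratio distributions, interaction-tier
coefficients of variation, and chimeric-complex correlations.

All bulk ratios are computed per replicate from raw read-count sums; spike
rows are always excluded. Dual-targeted genes are excluded from
single-organelle gene sets unless explicitly requested (``include_dual``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cytobalance.annotations import NUCLEAR_TARGETING_CLASSES, AnnotationSet
from cytobalance.quantify import CountTable, SampleMeta, tpm_ratio
from cytobalance.stats import pearson_r

logger = logging.getLogger(__name__)

# Nested interaction tiers, loosest to tightest. "other" covers nuclear
# genes without organelle targeting (targeting other/unknown); "targeted"
# covers all organelle-targeted nuclear genes regardless of tier.
CV_TIERS = ("other", "targeted", "complexed", "direct")


@dataclass(frozen=True)
class CompartmentRatio:
    sample_id: str
    numerator: str
    denominator: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("compartment ratio must be >= 0")


@dataclass(frozen=True)
class CVReport:
    tier: str
    n_genes: int
    cv: float


def _nuclear_genes(counts: CountTable, ann: AnnotationSet) -> list[str]:
    return [g for g in counts.genes if g in ann and ann[g].genome == "nuclear"]


def targeted_fraction(
    counts: CountTable,
    ann: AnnotationSet,
    targeting: str,
    sample_id: str,
) -> float:
    """Fraction of nuclear read counts from genes of one targeting class.

    Organellar and spike genes are excluded from both numerator and
    denominator; fractions over all five targeting classes sum to 1.
    """
    if targeting not in NUCLEAR_TARGETING_CLASSES:
        raise ValueError(f"unknown targeting class {targeting!r}")
    nuclear = _nuclear_genes(counts, ann)
    col = counts.counts[sample_id]
    total = int(col.loc[nuclear].sum())
    if total <= 0:
        raise ValueError(f"sample {sample_id!r} has zero nuclear reads")
    class_genes = [g for g in nuclear if ann[g].targeting == targeting]
    return float(col.loc[class_genes].sum()) / total


def organelle_nuclear_ratio(
    counts: CountTable,
    ann: AnnotationSet,
    genome: str,
    sample_id: str,
) -> CompartmentRatio:
    """Summed organellar-genome counts over summed nuclear counts."""
    if genome not in ("plastid", "mitochondrion"):
        raise ValueError(f"genome must be plastid or mitochondrion, got {genome!r}")
    col = counts.counts[sample_id]
    nuclear = _nuclear_genes(counts, ann)
    nuc_total = int(col.loc[nuclear].sum())
    if nuc_total <= 0:
        raise ValueError(f"sample {sample_id!r} has zero nuclear reads")
    org_genes = [g for g in counts.genes if g in ann and ann[g].genome == genome]
    value = float(col.loc[org_genes].sum()) / nuc_total
    return CompartmentRatio(sample_id, genome, "nuclear", value)


def balance_ratio(
    counts: CountTable,
    ann: AnnotationSet,
    genome: str,
    sample_id: str,
    include_dual: bool = False,
    exclude: Iterable[str] = (),
) -> CompartmentRatio:
    """Organellar-genome counts over counts of nuclear genes targeted there.

    ``include_dual`` adds dual-targeted genes to the nuclear denominator.
    ``exclude`` removes listed genes from the organellar numerator (used for
    single-gene sensitivity checks).
    """
    if genome not in ("plastid", "mitochondrion"):
        raise ValueError(f"genome must be plastid or mitochondrion, got {genome!r}")
    excluded = set(exclude)
    col = counts.counts[sample_id]
    classes = {genome, "dual"} if include_dual else {genome}
    targeted = [
        g
        for g in counts.genes
        if g in ann and ann[g].genome == "nuclear" and ann[g].targeting in classes
    ]
    targeted_total = int(col.loc[targeted].sum())
    if targeted_total <= 0:
        raise ValueError(f"sample {sample_id!r} has zero {genome}-targeted nuclear reads")
    org_genes = [
        g
        for g in counts.genes
        if g in ann and ann[g].genome == genome and g not in excluded
    ]
    value = float(col.loc[org_genes].sum()) / targeted_total
    label = f"{genome}_targeted" + ("_plus_dual" if include_dual else "")
    return CompartmentRatio(sample_id, genome, label, value)


def genome_tpm_ratios(
    mean_num: pd.Series,
    mean_den: pd.Series,
    ann: AnnotationSet,
    min_mean: float = 0.0,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-gene expression ratios grouped by genome of origin.

    Returns the :func:`tpm_ratio` frame restricted to genes with a known
    genome, minus any explicitly excluded genes.
    """
    df = tpm_ratio(mean_num, mean_den, ann, min_mean=min_mean)
    df = df[df["genome"].isin(["nuclear", "plastid", "mitochondrion"])]
    excluded = set(exclude)
    if excluded:
        df = df[~df.index.isin(excluded)]
    return df


def tier_of_ratios(ratios: pd.DataFrame, tier: str) -> pd.Series:
    """Select the ratio values belonging to one (nested) CV tier."""
    nuclear = ratios[ratios["genome"] == "nuclear"]
    targeted_mask = nuclear["targeting"].isin(["plastid", "mitochondrion", "dual"])
    if tier == "other":
        sel = nuclear[~targeted_mask]
    elif tier == "targeted":
        sel = nuclear[targeted_mask]
    elif tier == "complexed":
        sel = nuclear[nuclear["tier"].isin(["complexed", "direct"])]
    elif tier == "direct":
        sel = nuclear[nuclear["tier"] == "direct"]
    else:
        raise ValueError(f"unknown CV tier {tier!r}")
    return sel["ratio"]


def cv_by_tier(ratios: pd.DataFrame, tiers: Sequence[str] = CV_TIERS) -> list[CVReport]:
    """Coefficient of variation (n-1 sd / mean) of ratios per nested tier.

    Tiers with fewer than two genes are omitted with a warning.
    """
    reports = []
    for tier in tiers:
        values = tier_of_ratios(ratios, tier).to_numpy()
        if values.size < 2:
            logger.warning("tier %r has %d gene(s); omitted from CV report", tier, values.size)
            continue
        cv = float(np.std(values, ddof=1) / np.mean(values))
        reports.append(CVReport(tier=tier, n_genes=int(values.size), cv=cv))
    return reports


@dataclass(frozen=True)
class ComplexCorrelation:
    complex_id: str
    r_all: float
    n_all: int
    r_nuclear: float | None
    n_nuclear: int
    r_organellar: float | None
    n_organellar: int


def complex_correlation(
    mean_a: pd.Series,
    mean_b: pd.Series,
    members: Iterable[str],
    ann: AnnotationSet | None = None,
    complex_id: str = "",
) -> ComplexCorrelation:
    """Pearson r of (mean_b, mean_a) expression pairs over complex members.

    Also reports subgroup correlations for nuclear-encoded vs
    organelle-encoded subunits when annotations are given and the subgroup
    has at least three members. Degenerate (zero-variance) inputs raise.
    """
    members = [m for m in members if m in mean_a.index and m in mean_b.index]
    if len(members) < 3:
        raise ValueError(f"complex {complex_id!r}: need >= 3 quantified members, got {len(members)}")
    a = mean_a.loc[members].to_numpy()
    b = mean_b.loc[members].to_numpy()
    r_all = pearson_r(b, a)

    r_nuc = r_org = None
    n_nuc = n_org = 0
    if ann is not None:
        nuc = [m for m in members if m in ann and ann[m].genome == "nuclear"]
        org = [m for m in members if m in ann and ann[m].genome in ("plastid", "mitochondrion")]
        n_nuc, n_org = len(nuc), len(org)
        if n_nuc >= 3:
            r_nuc = pearson_r(mean_b.loc[nuc].to_numpy(), mean_a.loc[nuc].to_numpy())
        if n_org >= 3:
            r_org = pearson_r(mean_b.loc[org].to_numpy(), mean_a.loc[org].to_numpy())
    return ComplexCorrelation(
        complex_id=complex_id,
        r_all=r_all,
        n_all=len(members),
        r_nuclear=r_nuc,
        n_nuclear=n_nuc,
        r_organellar=r_org,
        n_organellar=n_org,
    )


def bulk_ratio_table(
    counts: CountTable,
    ann: AnnotationSet,
    meta: Sequence[SampleMeta],
) -> pd.DataFrame:
    """Per-replicate bulk ratios for both organelles, tidy format.

    One row per (sample, ratio kind): organelle/nuclear and balance ratios
    with and without dual-targeted genes.
    """
    rows = []
    by_id = {m.sample_id: m for m in meta}
    for sample_id in counts.samples:
        m = by_id.get(sample_id)
        for genome in ("plastid", "mitochondrion"):
            entries = [
                ("organelle_nuclear", organelle_nuclear_ratio(counts, ann, genome, sample_id)),
                ("balance", balance_ratio(counts, ann, genome, sample_id, include_dual=False)),
                ("balance_plus_dual", balance_ratio(counts, ann, genome, sample_id, include_dual=True)),
            ]
            for kind, cr in entries:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "organ": m.organ if m else "",
                        "ploidy": m.ploidy if m else "",
                        "genome": genome,
                        "ratio_kind": kind,
                        "value": cr.value,
                    }
                )
    return pd.DataFrame(rows)
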
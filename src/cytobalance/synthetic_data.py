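"""Generative model for tri-genome RNA-seq experiments with spike-ins.

Per cell and ploidy, a nuclear gene's transcript output is
``copies(ploidy) * base_rate * class_multiplier(ploidy) * gene noise``; an
organellar gene's output is ``organelle genomes per cell * per-genome rate *
coordination factor``; the spike pool is proportional to DNA per cell. A
library is a single multinomial draw of fixed size over all species after a
per-species gamma perturbation (gamma-multinomial negative binomial), so
counts sum exactly to the configured depth.

Organelle genomes per cell at ploidy p are
``diploid baseline * (p/2) * per-nuclear-genome response(p)``, which makes
the per-cell vs per-genome copy arithmetic an algebraic identity of the
model. The gene-level ratio noise of organelle-targeted nuclear genes is
damped by the interaction-tier coupling (variance fraction shared across the
tier), which is what drives the tier ordering of ratio CVs.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from cytobalance.annotations import AnnotationSet, classify_genome
from cytobalance.qpcr import QpcrPlate
from cytobalance.quantify import CountTable, SampleMeta
from cytobalance.spikenorm import SpikeDesign

PLOIDY_REL = {"2C": 1.0, "4C": 2.0, "8C": 4.0}


@dataclass
class ComplexSpec:
    """A protein complex: member gene ids with fixed per-cell expression rates."""

    complex_id: str
    organelle: str  # compartment the complex resides in (plastid | mitochondrion)
    chimeric: bool  # True if members span nuclear and organellar genomes
    members: dict[str, float]  # gene_id -> base rate (transcripts per cell, a.u.)

    def nuclear_members(self) -> list[str]:
        return [g for g in self.members if classify_genome(g) == "nuclear"]


@dataclass
class SimulationParams:
    """Full generative truth for one synthetic experiment."""

    n_nuclear_genes: int = 5000
    n_plastid_genes: int = 80
    n_mito_genes: int = 50
    n_spike_species: int = 92
    # targeting-class mix over plain nuclear genes (complex members extra)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "plastid": 0.12,
            "mitochondrion": 0.10,
            "dual": 0.06,
            "other": 0.52,
            "unknown": 0.20,
        }
    )
    # interaction-tier mix within organelle-targeted nuclear genes
    tier_proportions: dict[str, float] = field(
        default_factory=lambda: {"none": 0.50, "complexed": 0.30, "direct": 0.20}
    )
    # per-class log-normal base-rate parameters (meanlog, sdlog)
    base_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "plastid": (1.5, 1.2),
            "mitochondrion": (0.8, 1.2),
            "dual": (1.5, 1.2),
            "other": (0.0, 1.2),
            "unknown": (-0.5, 1.2),
        }
    )
    plastid_gene_rate: tuple[float, float] = (2.2, 1.0)
    mito_gene_rate: tuple[float, float] = (2.0, 1.0)
    spike_rate: tuple[float, float] = (0.0, 1.5)
    organ: str = "leaf"
    ploidy_levels: tuple[str, ...] = ("2C", "4C")
    reps_per_ploidy: int = 3
    # per-nuclear-genome organelle genome copy ratio relative to 2C
    organelle_genome_response: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "4C": {"plastid": 0.76, "mitochondrion": 1.01},
            "8C": {"plastid": 0.60, "mitochondrion": 0.95},
        }
    )
    # per-class mean per-genome-copy transcription multiplier vs 2C
    dosage_multiplier: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "4C": {
                "plastid": 0.90,
                "mitochondrion": 1.05,
                "dual": 0.95,
                "other": 1.10,
                "unknown": 1.10,
            },
            "8C": {
                "plastid": 0.80,
                "mitochondrion": 1.00,
                "dual": 0.90,
                "other": 1.15,
                "unknown": 1.15,
            },
        }
    )
    # fraction of a tier's ratio variance shared across the tier
    tier_coupling: dict[str, float] = field(
        default_factory=lambda: {"none": 0.55, "complexed": 0.88, "direct": 0.985}
    )
    ratio_noise_sd: float = 0.45  # log-scale sd of per-gene ratio noise (untargeted genes)
    tier_shared_sd: float = 0.02  # log-scale sd of the tier-shared ratio component
    organelle_gene_noise_sd: float = 0.05
    coordination_mode: dict[str, str] = field(
        default_factory=lambda: {"plastid": "coordinated", "mitochondrion": "boosted"}
    )
    # organelle output boost beyond the targeted-class multiplier (boosted mode)
    organelle_boost: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "4C": {"plastid": 1.0, "mitochondrion": 1.25},
            "8C": {"plastid": 1.0, "mitochondrion": 1.35},
        }
    )
    dispersion: float = 0.05  # NB overdispersion (gamma CV^2)
    depth: int = 5_000_000
    spike_fraction: float = 0.02  # expected spike read share in 2C libraries
    rna_per_dna: dict[str, float] | None = None  # per-ploidy; derived from truth if None
    qpcr_noise_sd: float = 0.02  # Cq cycles
    seed: int = 42
    complexes: list[ComplexSpec] = field(default_factory=lambda: default_complexes())

    # named organellar genes with fixed high rates (fractions of organelle output)
    mito_rrna_gene: str = "ATMG00020"
    mito_rrna_share: float = 0.45  # share of mitochondrial output from the rRNA gene

    def __post_init__(self) -> None:
        for name in ("n_nuclear_genes", "n_plastid_genes", "n_mito_genes", "n_spike_species"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if abs(sum(self.tier_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("tier_proportions must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 < self.spike_fraction < 1:
            raise ValueError("spike_fraction must be in (0, 1)")
        if self.reps_per_ploidy < 1:
            raise ValueError("reps_per_ploidy must be >= 1")
        if "2C" not in self.ploidy_levels:
            raise ValueError("ploidy_levels must include the 2C baseline")
        for p in self.ploidy_levels:
            if p not in PLOIDY_REL:
                raise ValueError(f"unknown ploidy level {p!r}")
            if p == "2C":
                continue
            if p not in self.organelle_genome_response or p not in self.dosage_multiplier:
                raise ValueError(f"no response/multiplier configured for ploidy {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ploidy_levels"] = list(self.ploidy_levels)
        d["base_rates"] = {k: list(v) for k, v in self.base_rates.items()}
        d["plastid_gene_rate"] = list(self.plastid_gene_rate)
        d["mito_gene_rate"] = list(self.mito_gene_rate)
        d["spike_rate"] = list(self.spike_rate)
        d["complexes"] = [dataclasses.asdict(c) for c in self.complexes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = copy.deepcopy(d)
        if "ploidy_levels" in d:
            d["ploidy_levels"] = tuple(d["ploidy_levels"])
        for key in ("plastid_gene_rate", "mito_gene_rate", "spike_rate"):
            if key in d:
                d[key] = tuple(d[key])
        if "base_rates" in d:
            d["base_rates"] = {k: tuple(v) for k, v in d["base_rates"].items()}
        if "complexes" in d:
            d["complexes"] = [
                c if isinstance(c, ComplexSpec) else ComplexSpec(**c) for c in d["complexes"]
            ]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(copy.deepcopy(self), **kwargs)


def default_complexes() -> list[ComplexSpec]:
    """Four reference complexes: three chimeric, one entirely nuclear.

    Rates span roughly two orders of magnitude so complex scatter plots are
    leverage-dominated, as for the highly expressed photosynthesis and
    OXPHOS machinery.
    """
    return [
        ComplexSpec(
            "RUBISCO",
            "plastid",
            True,
            {
                "ATCG00490": 700.0,  # large subunit, plastid-encoded
                "AT1G67090": 150.0,
                "AT5G38430": 60.0,
                "AT5G38420": 25.0,
                "AT5G38410": 12.0,
            },
        ),
        ComplexSpec(
            "PSII",
            "plastid",
            True,
            {
                "ATCG00020": 1200.0,  # psbA-like, plastid-encoded; dominates the complex
                "ATCG00270": 130.0,
                "ATCG00280": 90.0,
                "ATCG00580": 45.0,
                "ATCG00710": 18.0,
                "ATCG00080": 8.0,
                "AT5G66570": 120.0,
                "AT1G06680": 60.0,
                "AT4G21280": 28.0,
                "AT1G79040": 12.0,
                "AT2G30570": 5.0,
                "AT3G21055": 2.5,
            },
        ),
        ComplexSpec(
            "OXPHOS_III",
            "mitochondrion",
            True,
            {
                "ATMG00220": 200.0,  # cytochrome b, mito-encoded
                "AT3G27240": 60.0,
                "AT5G40810": 25.0,
                "AT4G32470": 10.0,
                "AT2G40765": 4.0,
                "AT1G51980": 1.7,
            },
        ),
        ComplexSpec(
            "OXPHOS_II",
            "mitochondrion",
            False,
            {
                "AT5G66760": 80.0,
                "AT3G27380": 30.0,
                "AT5G40650": 12.0,
                "AT1G08480": 5.0,
            },
        ),
    ]


def paper_calibrated() -> SimulationParams:
    """The shipped preset: printed copy-number responses (0.76 plastid,
    1.01 mitochondrion at 4C) with otherwise arbitrary but fixed defaults."""
    ref = resources.files("cytobalance") / "presets" / "paper_calibrated.yaml"
    with resources.as_file(ref) as path:
        return SimulationParams.from_yaml(path)


@dataclass
class SimulationTruth:
    """Realized generative quantities against which recovery is tested."""

    params: SimulationParams
    gene_multiplier: pd.DataFrame  # genes x non-2C ploidies, realized ratio multipliers
    class_multiplier: dict[str, dict[str, float]]  # ploidy -> class -> configured mean
    organelle_per_cell_ratio: dict[str, dict[str, float]]  # ploidy -> organelle -> output ratio
    organelle_genomes_per_cell: dict[str, dict[str, float]]  # ploidy -> organelle -> rel. copies
    total_output_ratio: dict[str, float]  # ploidy -> expected plant output per cell vs 2C
    rna_per_dna: dict[str, float]
    spike_scale: float
    expected_weights: pd.DataFrame  # species x ploidy expected per-cell read weights


def organelle_genomes_per_cell(ploidy: str, response: float, baseline: float = 1.0) -> float:
    """Organelle genome copies per cell: baseline * (p/2) * per-genome response."""
    return baseline * PLOIDY_REL[ploidy] * response


def _draw_lengths(rng: np.random.Generator, n: int, meanlog: float, sdlog: float) -> np.ndarray:
    return np.exp(rng.normal(meanlog, sdlog, size=n))


def _build_gene_universe(params: SimulationParams, rng: np.random.Generator):
    """Assign ids, classes, tiers, rates and lengths for every species."""
    classes = list(params.class_proportions)
    probs = np.array([params.class_proportions[c] for c in classes])
    n = params.n_nuclear_genes
    class_draw = rng.choice(len(classes), size=n, p=probs)

    reserved = {gid for cpx in params.complexes for gid in cpx.members}
    chroms = "12345"
    nuclear_ids = []
    i = 0
    while len(nuclear_ids) < n:
        gid = f"AT{chroms[i % 5]}G{(i // 5 + 1) * 10:05d}"
        i += 1
        if gid not in reserved:
            nuclear_ids.append(gid)
    rows = []
    for gid, ci in zip(nuclear_ids, class_draw):
        cls = classes[ci]
        if cls in ("plastid", "mitochondrion", "dual"):
            tiers = list(params.tier_proportions)
            tier = tiers[rng.choice(len(tiers), p=np.array([params.tier_proportions[t] for t in tiers]))]
        else:
            tier = "none"
        meanlog, sdlog = params.base_rates[cls]
        rate = float(np.exp(rng.normal(meanlog, sdlog)))
        rows.append((gid, "nuclear", cls, tier, None, rate))

    # complex members: nuclear ones appended with fixed rates, organellar ones
    # merged into the organelle gene sets below
    complex_nuclear: dict[str, tuple[str, str, float]] = {}
    complex_organellar: dict[str, tuple[str, str, float]] = {}
    complex_of: dict[str, str] = {}
    for cpx in params.complexes:
        for gid, rate in cpx.members.items():
            genome = classify_genome(gid)
            complex_of[gid] = cpx.complex_id
            if genome == "nuclear":
                tier = "direct" if cpx.chimeric else "none"
                complex_nuclear[gid] = (cpx.organelle, tier, rate)
            else:
                if genome != cpx.organelle:
                    raise ValueError(
                        f"complex {cpx.complex_id}: member {gid} is {genome}, not {cpx.organelle}"
                    )
                complex_organellar[gid] = (genome, cpx.complex_id, rate)
    for gid, (targeting, tier, rate) in complex_nuclear.items():
        rows.append((gid, "nuclear", targeting, tier, complex_of[gid], rate))

    plastid_ids = [f"ATCG{(i + 1) * 10:05d}" for i in range(params.n_plastid_genes)]
    mito_ids = [f"ATMG{(i + 1) * 10:05d}" for i in range(params.n_mito_genes)]
    for gid in plastid_ids:
        meanlog, sdlog = params.plastid_gene_rate
        rate = float(np.exp(rng.normal(meanlog, sdlog)))
        rows.append((gid, "plastid", "not_applicable", "none", complex_of.get(gid), rate))
    for gid in mito_ids:
        meanlog, sdlog = params.mito_gene_rate
        rate = float(np.exp(rng.normal(meanlog, sdlog)))
        rows.append((gid, "mitochondrion", "not_applicable", "none", complex_of.get(gid), rate))
    for gid, (genome, cid, rate) in complex_organellar.items():
        if gid not in plastid_ids and gid not in mito_ids:
            rows.append((gid, genome, "not_applicable", "none", cid, rate))
        else:  # override the drawn rate for a named organellar complex member
            for i, r in enumerate(rows):
                if r[0] == gid:
                    rows[i] = (gid, genome, "not_applicable", "none", cid, rate)

    spike_ids = [f"ERCC-{i + 1:05d}" for i in range(params.n_spike_species)]
    for gid in spike_ids:
        meanlog, sdlog = params.spike_rate
        rate = float(np.exp(rng.normal(meanlog, sdlog)))
        rows.append((gid, "spike", "not_applicable", "none", None, rate))

    df = pd.DataFrame(
        rows, columns=["gene_id", "genome", "targeting", "tier", "complex", "rate"]
    ).set_index("gene_id")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"gene id collision in simulated universe: {dupes}")

    # pin the mitochondrial rRNA-like gene to its configured share of output
    if params.mito_rrna_gene in df.index:
        mito_mask = df["genome"] == "mitochondrion"
        other_mito = df.loc[mito_mask & (df.index != params.mito_rrna_gene), "rate"].sum()
        share = params.mito_rrna_share
        df.loc[params.mito_rrna_gene, "rate"] = share / (1.0 - share) * other_mito

    lengths = np.empty(len(df))
    for genome, (ml, sl) in (
        ("nuclear", (0.30, 0.35)),
        ("plastid", (0.05, 0.30)),
        ("mitochondrion", (0.05, 0.30)),
        ("spike", (-0.35, 0.30)),
    ):
        mask = (df["genome"] == genome).to_numpy()
        lengths[mask] = _draw_lengths(rng, int(mask.sum()), ml, sl)
    df["length_kb"] = lengths
    return df


def _ratio_multipliers(
    params: SimulationParams, universe: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Realized per-gene-copy ratio multipliers vs 2C for every non-2C ploidy.

    Nuclear genes: class mean multiplier times log-normal noise whose
    gene-specific variance is damped by the tier coupling; a small shared
    per-tier component models coordinated regulation. Organellar genes get
    the compartment's per-cell output ratio divided by the nuclear dosage
    change (so that per-cell weight = ploidy * rate * multiplier holds for
    every plant gene), times small gene noise. Spikes stay at 1.
    """
    ploidies = [p for p in params.ploidy_levels if p != "2C"]
    mult = pd.DataFrame(1.0, index=universe.index, columns=ploidies if ploidies else ["_none"])
    if not ploidies:
        return mult.drop(columns=["_none"])
    genomes = universe["genome"].to_numpy()
    targeting = universe["targeting"].to_numpy()
    tiers = universe["tier"].to_numpy()
    n = len(universe)
    for p in ploidies:
        shared = {
            tier: rng.normal(0.0, params.tier_shared_sd * np.sqrt(c))
            for tier, c in params.tier_coupling.items()
        }
        values = np.ones(n)
        for i in range(n):
            if genomes[i] == "nuclear":
                cls = targeting[i]
                m = params.dosage_multiplier[p][cls]
                if cls in ("plastid", "mitochondrion", "dual"):
                    coupling = params.tier_coupling[tiers[i]]
                    shared_part = shared[tiers[i]]
                else:
                    coupling = 0.0
                    shared_part = 0.0
                eps = rng.normal(0.0, params.ratio_noise_sd * np.sqrt(1.0 - coupling))
                values[i] = m * np.exp(shared_part + eps)
            elif genomes[i] in ("plastid", "mitochondrion"):
                per_cell = _organelle_output_ratio(params, genomes[i], p)
                eps = rng.normal(0.0, params.organelle_gene_noise_sd)
                values[i] = per_cell / PLOIDY_REL[p] * np.exp(eps)
        mult[p] = values
    return mult


def _organelle_output_ratio(params: SimulationParams, organelle: str, ploidy: str) -> float:
    """Per-cell organelle transcriptional output at `ploidy` relative to 2C."""
    m_targeted = params.dosage_multiplier[ploidy][organelle]
    mode = params.coordination_mode[organelle]
    boost = 1.0 if mode == "coordinated" else params.organelle_boost[ploidy][organelle]
    return PLOIDY_REL[ploidy] * m_targeted * boost


def simulate_experiment(
    params: SimulationParams,
) -> tuple[CountTable, AnnotationSet, list[SampleMeta], list[SpikeDesign], SimulationTruth]:
    """Draw a full synthetic experiment from the generative model."""
    rng = np.random.default_rng(params.seed)
    universe = _build_gene_universe(params, rng)
    mult = _ratio_multipliers(params, universe, rng)

    genomes = universe["genome"].to_numpy()
    rates = universe["rate"].to_numpy()
    lengths = universe["length_kb"].to_numpy()
    is_spike = genomes == "spike"

    # per-cell expected read weight of each species, by ploidy
    weights = {}
    org_per_cell = {}
    org_genomes = {}
    for p in params.ploidy_levels:
        w = rates * lengths  # read weight ~ transcript rate x length
        if p != "2C":
            # per-cell plant output: ploidy x per-genome-copy multiplier
            m = mult[p].to_numpy()
            w = w * np.where(is_spike, 1.0, PLOIDY_REL[p] * m)
        org_per_cell[p] = {
            org: (1.0 if p == "2C" else _organelle_output_ratio(params, org, p))
            for org in ("plastid", "mitochondrion")
        }
        org_genomes[p] = {
            org: organelle_genomes_per_cell(
                p, 1.0 if p == "2C" else params.organelle_genome_response[p][org]
            )
            for org in ("plastid", "mitochondrion")
        }
        weights[p] = w

    # spike pool proportional to DNA per cell; calibrated to the 2C share
    plant_total_2c = weights["2C"][~is_spike].sum()
    spike_raw_2c = weights["2C"][is_spike].sum()
    spike_scale = (
        params.spike_fraction / (1.0 - params.spike_fraction) * plant_total_2c / spike_raw_2c
    )
    for p in params.ploidy_levels:
        dna_per_cell = PLOIDY_REL[p]
        weights[p] = weights[p].copy()
        weights[p][is_spike] = (
            universe.loc[is_spike, "rate"].to_numpy()
            * universe.loc[is_spike, "length_kb"].to_numpy()
            * spike_scale
            * dna_per_cell
        )

    total_output = {
        p: float(weights[p][~is_spike].sum() / weights["2C"][~is_spike].sum())
        for p in params.ploidy_levels
    }
    if params.rna_per_dna is not None:
        rna_per_dna = dict(params.rna_per_dna)
    else:
        # transcriptome size: plant output per cell / DNA per cell, 2C == 10
        rna_per_dna = {
            p: 10.0 * total_output[p] / PLOIDY_REL[p] for p in params.ploidy_levels
        }

    # draw libraries
    samples, meta, designs = [], [], []
    count_cols = {}
    shape = 1.0 / params.dispersion if params.dispersion > 0 else None
    for p in params.ploidy_levels:
        for rep in range(1, params.reps_per_ploidy + 1):
            sid = f"{params.organ}_{p}_r{rep}"
            w = weights[p]
            if shape is not None:
                # biological overdispersion applies to plant transcripts only;
                # spikes come from a common stock and vary only with sampling
                gamma = rng.gamma(shape, 1.0 / shape, size=w.size)
                w = w * np.where(is_spike, 1.0, gamma)
            probs = w / w.sum()
            count_cols[sid] = rng.multinomial(params.depth, probs)
            meta.append(
                SampleMeta(
                    sample_id=sid,
                    organ=params.organ,
                    ploidy=p,
                    replicate=rep,
                    rna_per_dna=rna_per_dna[p],
                    spike_mix="mix1",
                )
            )
            designs.append(
                SpikeDesign(
                    sample_id=sid,
                    rna_mass=1.0,
                    rna_per_dna=rna_per_dna[p],
                    spike_mass=1.0 / rna_per_dna[p],
                )
            )
            samples.append(sid)

    counts_df = pd.DataFrame(count_cols, index=universe.index)
    counts = CountTable(
        counts=counts_df, spike_flags=pd.Series(is_spike, index=universe.index)
    )

    targeting_map = {
        gid: (row["targeting"], row["tier"], row["complex"] if pd.notna(row["complex"]) else None)
        for gid, row in universe.iterrows()
    }
    ann = AnnotationSet.build(
        lengths=universe["length_kb"].to_dict(),
        targeting=targeting_map,
        provenance={"source": "simulate_experiment", "seed": params.seed},
    )

    expected = pd.DataFrame(
        {p: weights[p] for p in params.ploidy_levels}, index=universe.index
    )
    truth = SimulationTruth(
        params=params,
        gene_multiplier=mult,
        class_multiplier={
            p: dict(params.dosage_multiplier[p])
            for p in params.ploidy_levels
            if p != "2C"
        },
        organelle_per_cell_ratio=org_per_cell,
        organelle_genomes_per_cell=org_genomes,
        total_output_ratio=total_output,
        rna_per_dna=rna_per_dna,
        spike_scale=float(spike_scale),
        expected_weights=expected,
    )
    return counts, ann, meta, designs, truth


QPCR_REFERENCES = ("AT2G10940", "AT1G69960")
QPCR_TARGETS = {"ATCG00490": "plastid", "ATMG00020": "mitochondrion"}
_QPCR_BASE_CQ = {"AT2G10940": 20.0, "AT1G69960": 22.0, "ATCG00490": 14.0, "ATMG00020": 16.0}


def simulate_qpcr(params: SimulationParams, efficiency: float = 2.0) -> QpcrPlate:
    """Synthetic qPCR plates for organelle copy-number estimation.

    Template copies per sample: nuclear references scale with nuclear
    ploidy; organellar targets scale with nuclear ploidy times the
    configured per-genome response. Cq = base - log_eff(copies) + noise.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    ploidy_of = {}
    for p in params.ploidy_levels:
        for rep in range(1, params.reps_per_ploidy + 1):
            sid = f"q_{p}_r{rep}"
            ploidy_of[sid] = p
            for gene in (*QPCR_REFERENCES, *QPCR_TARGETS):
                if gene in QPCR_TARGETS:
                    org = QPCR_TARGETS[gene]
                    response = (
                        1.0 if p == "2C" else params.organelle_genome_response[p][org]
                    )
                    copies = PLOIDY_REL[p] * response
                else:
                    copies = PLOIDY_REL[p]
                cq = (
                    _QPCR_BASE_CQ[gene]
                    - np.log(copies) / np.log(efficiency)
                    + rng.normal(0.0, params.qpcr_noise_sd)
                )
                rows.append({"gene_id": gene, "sample_id": sid, "Cq": float(cq)})
    return QpcrPlate(
        wells=pd.DataFrame(rows),
        references=list(QPCR_REFERENCES),
        targets=list(QPCR_TARGETS),
        ploidy=ploidy_of,
        efficiency=efficiency,
    )
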
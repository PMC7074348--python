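"""Relative organelle-genome copy number from qPCR Cq values.

Copy number of an organellar target is normalized to the geometric mean of
two (or more) nuclear reference genes and compared between ploidies by the
delta-delta-Cq method. On the Cq scale the geometric mean of quantities is
the arithmetic mean of cycles, so the per-sample normalizer is
mean(reference Cq); fold change between ploidies is
efficiency ** -(dCq_num - dCq_den).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class QpcrPlate:
    """Cq measurements with gene roles and per-sample ploidy."""

    wells: pd.DataFrame  # columns: gene_id, sample_id, Cq
    references: list[str]
    targets: list[str]
    ploidy: dict[str, str]  # sample_id -> ploidy label
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        required = {"gene_id", "sample_id", "Cq"}
        if not required <= set(self.wells.columns):
            raise ValueError(f"wells must have columns {sorted(required)}")
        if (self.wells["Cq"] <= 0).any():
            raise ValueError("Cq values must be positive")
        if len(self.references) < 2:
            raise ValueError("need at least two reference genes")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError(f"efficiency must be in (1, 2], got {self.efficiency}")
        for sample_id in self.wells["sample_id"].unique():
            if sample_id not in self.ploidy:
                raise ValueError(f"no ploidy recorded for sample {sample_id!r}")
            measured = set(
                self.wells.loc[self.wells["sample_id"] == sample_id, "gene_id"]
            )
            missing = set(self.references) - measured
            if missing:
                raise ValueError(
                    f"sample {sample_id!r} missing reference wells: {sorted(missing)}"
                )

    def samples_of(self, ploidy: str) -> list[str]:
        return sorted(s for s, p in self.ploidy.items() if p == ploidy)

    def delta_cq(self, target: str, sample_id: str) -> float:
        """Cq(target) minus the arithmetic mean of reference Cqs."""
        sub = self.wells[self.wells["sample_id"] == sample_id].set_index("gene_id")["Cq"]
        if target not in sub.index:
            raise ValueError(f"sample {sample_id!r} has no well for target {target!r}")
        ref_mean = float(np.mean([sub.loc[r] for r in self.references]))
        return float(sub.loc[target]) - ref_mean

    def write_tsv(self, path: str | Path) -> None:
        out = self.wells.copy()
        roles = {g: "reference" for g in self.references}
        roles.update({g: "target" for g in self.targets})
        out["role"] = out["gene_id"].map(roles)
        out["ploidy"] = out["sample_id"].map(self.ploidy)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, efficiency: float = 2.0) -> "QpcrPlate":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
        refs = sorted(df.loc[df["role"] == "reference", "gene_id"].unique())
        targets = sorted(df.loc[df["role"] == "target", "gene_id"].unique())
        ploidy = dict(zip(df["sample_id"], df["ploidy"]))
        return cls(
            wells=df[["gene_id", "sample_id", "Cq"]].copy(),
            references=refs,
            targets=targets,
            ploidy=ploidy,
            efficiency=efficiency,
        )


@dataclass(frozen=True)
class FoldChange:
    target: str
    ploidy_num: str
    ploidy_den: str
    fold: float
    se: float
    n: int
    folds: tuple[float, ...] = field(default=(), compare=False)


def relative_copy_number(
    plate: QpcrPlate,
    target: str,
    ploidy_num: str,
    ploidy_den: str,
) -> FoldChange:
    """Fold change of target copy number (ploidy_num vs ploidy_den).

    Replicates are paired by index across ploidies; each pair yields
    fold = efficiency ** -(dCq_num - dCq_den), and the mean fold and its
    standard error across pairs are reported. With unequal replicate
    counts the mean-dCq-per-ploidy form is used instead (n = 1, se = nan).
    """
    num_samples = plate.samples_of(ploidy_num)
    den_samples = plate.samples_of(ploidy_den)
    if not num_samples or not den_samples:
        raise ValueError(f"both ploidies must have samples: {ploidy_num}, {ploidy_den}")
    d_num = [plate.delta_cq(target, s) for s in num_samples]
    d_den = [plate.delta_cq(target, s) for s in den_samples]
    eff = plate.efficiency
    if len(d_num) == len(d_den):
        folds = np.array([eff ** -(a - b) for a, b in zip(d_num, d_den)])
        fold = float(folds.mean())
        se = float(folds.std(ddof=1) / np.sqrt(folds.size)) if folds.size > 1 else float("nan")
        return FoldChange(target, ploidy_num, ploidy_den, fold, se, folds.size, tuple(folds))
    ddcq = float(np.mean(d_num) - np.mean(d_den))
    fold = float(eff**-ddcq)
    return FoldChange(target, ploidy_num, ploidy_den, fold, float("nan"), 1, (fold,))


def copy_number_table(
    plate: QpcrPlate, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Fold-change results for every target over the requested ploidy pairs."""
    rows = []
    for target in plate.targets:
        for num, den in pairs:
            fc = relative_copy_number(plate, target, num, den)
            rows.append(
                {
                    "target": target,
                    "pair": f"{num}/{den}",
                    "fold": fc.fold,
                    "se": fc.se,
                    "n": fc.n,
                }
            )
    return pd.DataFrame(rows)
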
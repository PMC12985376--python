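"""Biophysical input measurements: abundances, bound fractions, residence times.

A :class:`MeasurementSet` is the model's sole empirical input: for each of
RAD21, NIPBL, PDS5 and WAPL it holds the absolute nuclear copy number, the
FRAP-derived chromatin-bound fraction and the mean chromatin residence time,
plus the genome size used to convert copy numbers into genomic densities.

The packaged HeLa wild-type table is available via :func:`hela_wildtype`
(see ``burstex/data/hela_wildtype.tsv``).  Synthetic tables for testing and
robustness analyses are produced by :func:`synthetic_measurements`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ProteinMeasurement",
    "MeasurementSet",
    "REQUIRED_PROTEINS",
    "REGULATOR_PROTEINS",
    "hela_wildtype",
    "synthetic_measurements",
]

REQUIRED_PROTEINS = ("RAD21", "NIPBL", "PDS5", "WAPL")
REGULATOR_PROTEINS = ("NIPBL", "PDS5", "WAPL")

#: Average diploid HeLa genome size (bp) used to convert copies to densities.
DEFAULT_GENOME_SIZE_BP = 19.539e9


@dataclass(frozen=True)
class ProteinMeasurement:
    """Copy number, chromatin-bound fraction and residence time of one protein."""

    name: str
    copy_number: float
    bound_fraction: float
    residence_time_s: float

    def __post_init__(self) -> None:
        if self.copy_number <= 0:
            raise ValueError(f"{self.name}: copy_number must be positive")
        if not 0.0 < self.bound_fraction < 1.0:
            raise ValueError(f"{self.name}: bound_fraction must lie strictly in (0, 1)")
        if self.residence_time_s <= 0:
            raise ValueError(f"{self.name}: residence_time_s must be positive")


@dataclass(frozen=True)
class MeasurementSet:
    """Per-protein measurements for RAD21, NIPBL, PDS5 and WAPL.

    The feasibility invariant enforces that the total amount of
    regulator-bound cohesin implied by the bound fractions cannot exceed
    the loaded cohesin population — under strict regulator exchange every
    chromatin-bound regulator molecule occupies one loaded complex.
    """

    proteins: Mapping[str, ProteinMeasurement]
    genome_size_bp: float = DEFAULT_GENOME_SIZE_BP

    def __post_init__(self) -> None:
        missing = [p for p in REQUIRED_PROTEINS if p not in self.proteins]
        if missing:
            raise ValueError(f"missing required proteins: {missing}")
        if self.genome_size_bp <= 0:
            raise ValueError("genome_size_bp must be positive")
        object.__setattr__(self, "proteins", dict(self.proteins))

    def __getitem__(self, name: str) -> ProteinMeasurement:
        return self.proteins[name]

    # -- derived quantities (normalized concentration convention) ---------

    def total(self, name: str) -> float:
        """Total abundance of ``name`` as a fraction of total RAD21."""
        return self.proteins[name].copy_number / self.proteins["RAD21"].copy_number

    def bound_amount(self, name: str) -> float:
        """Chromatin-bound abundance, as a fraction of total RAD21."""
        return self.proteins[name].bound_fraction * self.total(name)

    def free_amount(self, name: str) -> float:
        """Free (unbound) abundance, as a fraction of total RAD21."""
        return (1.0 - self.proteins[name].bound_fraction) * self.total(name)

    @property
    def feasible(self) -> bool:
        """Regulator-bound cohesin does not exceed loaded cohesin."""
        bound_regs = sum(self.bound_amount(x) for x in REGULATOR_PROTEINS)
        return bound_regs < self.bound_amount("RAD21")

    def loaded_density_per_mb(self) -> float:
        """Chromatin-loaded cohesin complexes per megabase of genome."""
        r = self.proteins["RAD21"]
        return r.bound_fraction * r.copy_number / self.genome_size_bp * 1e6

    # -- construction / IO -------------------------------------------------

    def with_scaled(self, factors: Mapping[str, float]) -> "MeasurementSet":
        """Return a copy with copy numbers multiplied by per-protein factors."""
        newp = {}
        for name, m in self.proteins.items():
            f = factors.get(name, 1.0)
            newp[name] = replace(m, copy_number=m.copy_number * f)
        return MeasurementSet(newp, self.genome_size_bp)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, genome_size_bp: float = DEFAULT_GENOME_SIZE_BP
    ) -> "MeasurementSet":
        required = {"protein", "copy_number", "bound_fraction", "residence_time_s"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"measurement table missing columns: {sorted(missing)}")
        proteins = {
            str(row.protein): ProteinMeasurement(
                name=str(row.protein),
                copy_number=float(row.copy_number),
                bound_fraction=float(row.bound_fraction),
                residence_time_s=float(row.residence_time_s),
            )
            for row in df.itertuples()
        }
        return cls(proteins, genome_size_bp)

    @classmethod
    def from_tsv(
        cls, path: str | Path, genome_size_bp: float = DEFAULT_GENOME_SIZE_BP
    ) -> "MeasurementSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"), genome_size_bp)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein": m.name,
                "copy_number": m.copy_number,
                "bound_fraction": m.bound_fraction,
                "residence_time_s": m.residence_time_s,
            }
            for m in self.proteins.values()
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def hela_wildtype() -> MeasurementSet:
    """The packaged wild-type HeLa measurement table.

    Copy numbers average mass-spectrometry and FCS quantifications; bound
    fractions and residence times come from FRAP, with the PDS5 A/B
    paralogs amalgamated.
    """
    ref = importlib.resources.files("burstex").joinpath("data/hela_wildtype.tsv")
    with importlib.resources.as_file(ref) as path:
        return MeasurementSet.from_tsv(path)


def synthetic_measurements(
    rng: np.random.Generator | int | None = None,
    *,
    require_feasible: bool = True,
    genome_size_bp: float = DEFAULT_GENOME_SIZE_BP,
) -> MeasurementSet:
    """Draw a random, physically plausible measurement table.

    Copy numbers are log-uniform in a HeLa-like range (3e4 to 5e5 for
    RAD21; regulators scaled below it), bound fractions uniform in
    (0.1, 0.9), residence times log-uniform between 20 s and 200 s for
    regulators and 300 s to 3000 s for RAD21.  With ``require_feasible``
    the draw is rejected until the regulator-bound total stays below the
    loaded cohesin population.
    """
    rng = np.random.default_rng(rng)
    for _ in range(1000):
        rad_copies = 10 ** rng.uniform(np.log10(3e4), np.log10(5e5))
        proteins = {
            "RAD21": ProteinMeasurement(
                "RAD21",
                rad_copies,
                rng.uniform(0.3, 0.9),
                10 ** rng.uniform(np.log10(300.0), np.log10(3000.0)),
            )
        }
        for reg in REGULATOR_PROTEINS:
            proteins[reg] = ProteinMeasurement(
                reg,
                rad_copies * rng.uniform(0.1, 0.8),
                rng.uniform(0.1, 0.9),
                10 ** rng.uniform(np.log10(20.0), np.log10(200.0)),
            )
        ms = MeasurementSet(proteins, genome_size_bp)
        if not require_feasible or ms.feasible:
            return ms
    raise RuntimeError("failed to draw a feasible measurement set")
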
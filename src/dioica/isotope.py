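"""Wood carbon-isotope ratios and discrimination against ¹³C.

δ¹³C expresses the ¹³C/¹²C ratio of a sample relative to the PDB standard in
per mille; discrimination Δ¹³C measures how strongly the plant discriminated
against ¹³C relative to the air it assimilated,

    Δ¹³C = (δ_air − δ_wood) / (1 + δ_wood/1000)   [‰],

the classical two-step model with per-mille deltas.  Δ¹³C is inversely
related to intrinsic water-use efficiency, which is why it carries the
ecophysiological signal analysed downstream.  Wood is measured on 5-year
blocks (pentads); the atmospheric reference δ¹³C_air — which declines
through the 20th century as fossil carbon dilutes the atmosphere — is
averaged onto the same pentads before the formula is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError

__all__ = [
    "AirDeltaSeries",
    "WoodIsotopeRecord",
    "delta13c_from_ratios",
    "discrimination",
    "solve_delta_wood",
    "air_delta_for_pentad",
    "attach_discrimination",
    "read_wood_isotopes",
    "write_wood_isotopes",
    "read_air_delta",
    "write_air_delta",
]


@dataclass
class AirDeltaSeries:
    """Annual atmospheric δ¹³C (‰ vs PDB), strictly increasing years."""

    years: np.ndarray
    delta_air: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.delta_air = np.asarray(self.delta_air, dtype=float)
        if len(self.years) != len(self.delta_air):
            raise ValidationError("years and delta_air lengths differ")
        if np.any(np.diff(self.years) <= 0):
            raise ValidationError("air-series years must be strictly increasing")

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.delta_air, index=self.years, name="delta_air")


@dataclass
class WoodIsotopeRecord:
    """One tree-pentad holocellulose measurement (δ¹³C ‰ vs PDB)."""

    tree_id: str
    pentad_start_year: int
    delta_wood: float
    delta13c: float | None = field(default=None)  # Δ¹³C, populated later


def delta13c_from_ratios(r_sample: float, r_standard: float) -> float:
    """δ¹³C = (R_sample/R_standard − 1) × 1000, in ‰."""
    if r_sample <= 0 or r_standard <= 0:
        raise ValidationError("isotope ratios must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def discrimination(delta_wood, delta_air):
    """Δ¹³C (‰) from per-mille wood and air δ¹³C values.

    Accepts scalars or arrays.  Strictly increasing in δ_air, strictly
    decreasing in δ_wood on the plausible domain (δ_wood > −1000 ‰).
    """
    delta_wood = np.asarray(delta_wood, dtype=float)
    if np.any(delta_wood <= -1000):
        raise ValidationError("delta_wood must exceed -1000 permil")
    out = (np.asarray(delta_air, dtype=float) - delta_wood) / (1.0 + delta_wood / 1000.0)
    return float(out) if out.ndim == 0 else out


def solve_delta_wood(delta13c, delta_air):
    """Invert the discrimination formula: δ_wood given Δ¹³C and δ_air (‰)."""
    d = np.asarray(delta13c, dtype=float)
    out = (np.asarray(delta_air, dtype=float) - d) / (1.0 + d / 1000.0)
    return float(out) if out.ndim == 0 else out


def air_delta_for_pentad(air: AirDeltaSeries, pentad_start_year: int) -> float:
    """Mean annual δ¹³C_air over the years of a pentad the series covers.

    Interior gaps are filled by linear interpolation before averaging; a
    pentad entirely outside the series raises :class:`CoverageError`.
    """
    years = np.arange(pentad_start_year, pentad_start_year + 5)
    covered = (years >= air.years.min()) & (years <= air.years.max())
    if not covered.any():
        raise CoverageError(
            f"pentad {pentad_start_year} outside air series "
            f"{air.years.min()}-{air.years.max()}"
        )
    values = np.interp(years[covered], air.years, air.delta_air)
    return float(values.mean())


def attach_discrimination(
    records: Iterable[WoodIsotopeRecord], air: AirDeltaSeries
) -> list[WoodIsotopeRecord]:
    """Populate ``delta13c`` on every record from its pentad's air mean."""
    out = []
    for rec in records:
        d_air = air_delta_for_pentad(air, rec.pentad_start_year)
        rec.delta13c = discrimination(rec.delta_wood, d_air)
        out.append(rec)
    return out


def read_wood_isotopes(path: str | Path) -> list[WoodIsotopeRecord]:
    """Read the wood-isotope CSV (tree_id, pentad_start_year, delta_wood_permil)."""
    df = pd.read_csv(path)
    required = {"tree_id", "pentad_start_year", "delta_wood_permil"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"wood-isotope CSV missing columns: {sorted(missing)}")
    return [
        WoodIsotopeRecord(
            tree_id=str(r.tree_id),
            pentad_start_year=int(r.pentad_start_year),
            delta_wood=float(r.delta_wood_permil),
        )
        for r in df.itertuples(index=False)
    ]


def write_wood_isotopes(records: Sequence[WoodIsotopeRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "tree_id": r.tree_id,
                "pentad_start_year": r.pentad_start_year,
                "delta_wood_permil": r.delta_wood,
            }
            for r in records
        ]
    ).to_csv(path, index=False, float_format="%.6g")
    return path


def read_air_delta(path: str | Path) -> AirDeltaSeries:
    """Read the annual atmospheric δ¹³C CSV (year, delta_air_permil)."""
    df = pd.read_csv(path)
    required = {"year", "delta_air_permil"}
    if required - set(df.columns):
        raise ValidationError(f"air CSV must have columns {sorted(required)}")
    df = df.sort_values("year")
    return AirDeltaSeries(df["year"].to_numpy(), df["delta_air_permil"].to_numpy())


def write_air_delta(air: AirDeltaSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"year": air.years, "delta_air_permil": air.delta_air}).to_csv(
        path, index=False, float_format="%.6g"
    )
    return path
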
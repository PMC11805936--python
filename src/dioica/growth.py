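"""Ring widths to basal-area increments, standardized chronologies and pentads.

Basal area increment (BAI, cm² yr⁻¹) is the annulus area a stem adds in one
year, π(r_t² − r_{t−1}²) with r the cumulative radius.  Because BAI of mature
trees tends to drift linearly with age, each tree-level BAI series is
standardized by dividing through an OLS line fitted against calendar year
(ratio indices, dimensionless, mean ≈ 1); the per-sex chronology is the
year-by-year arithmetic mean of those indices.  Five-year calendar blocks
("pentads", anchored at years divisible by 5) carry the growth values onto
the grid on which wood isotopes are measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DetrendingError, ValidationError
from .ringdata import RingWidthSeries, TreeRecord

__all__ = [
    "BaiSeries",
    "IndexChronology",
    "bai_from_widths",
    "tree_mean_bai",
    "detrend_linear",
    "build_chronology",
    "aggregate_pentads",
    "pentad_start",
    "reconstruct_historical_diameter",
    "estimate_age",
]


@dataclass
class BaiSeries:
    """Annual basal-area increments (cm² yr⁻¹) for one tree or core."""

    tree_id: str
    first_year: int
    bai: np.ndarray

    def __post_init__(self) -> None:
        self.bai = np.asarray(self.bai, dtype=float)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.bai))

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.bai, index=self.years, name=self.tree_id)


@dataclass
class IndexChronology:
    """Per-year mean standardized growth index for one sex group."""

    group_label: str
    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.index, index=self.years, name=self.group_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "index": self.index, "depth": self.sample_depth}
        )


def bai_from_widths(series: RingWidthSeries, pith_offset_mm: float = 0.0) -> BaiSeries:
    """Convert ring widths (mm) into annual BAI (cm²), accumulating from the pith.

    ``pith_offset_mm`` is radius already present before the first measured
    ring (0 when the core reached the pith).  With r_t the cumulative radius
    in cm, bai_t = π(r_t² − r_{t−1}²).
    """
    if pith_offset_mm < 0:
        raise ValidationError("pith_offset_mm must be >= 0")
    if np.any(series.widths < 0):
        raise ValidationError(f"series {series.series_id}: negative width")
    r = (pith_offset_mm + np.cumsum(series.widths)) / 10.0  # mm -> cm
    r_prev = np.concatenate([[pith_offset_mm / 10.0], r[:-1]])
    return BaiSeries(series.tree_id, series.first_year, np.pi * (r**2 - r_prev**2))


def tree_mean_bai(core_bai: Sequence[BaiSeries]) -> BaiSeries:
    """Per-year arithmetic mean of a tree's core BAI series."""
    if not core_bai:
        raise ValidationError("need at least one core series")
    frame = pd.DataFrame({i: b.to_pandas() for i, b in enumerate(core_bai)})
    mean = frame.mean(axis=1)
    return BaiSeries(core_bai[0].tree_id, int(mean.index[0]), mean.to_numpy())


def detrend_linear(series: BaiSeries, fallback: str = "difference") -> pd.Series:
    """Standardize a BAI series by an OLS line against calendar year.

    Returns ratio indices bai/fitted.  If the fitted line is nonpositive
    anywhere over the series, ratio detrending is impossible; with
    ``fallback='difference'`` the difference convention bai − fitted + 1 is
    used instead (flagged via the returned series' ``attrs['fallback']``),
    with ``fallback='error'`` a :class:`DetrendingError` is raised.
    """
    if len(series.bai) < 3:
        raise ValidationError("need >= 3 years to detrend")
    years = series.years.astype(float)
    slope, intercept = np.polyfit(years, series.bai, 1)
    fitted = intercept + slope * years
    used_fallback = False
    if np.any(fitted <= 0):
        if fallback == "error":
            raise DetrendingError(
                f"tree {series.tree_id}: fitted line nonpositive; "
                "use difference detrending"
            )
        index = series.bai - fitted + 1.0
        used_fallback = True
    else:
        index = series.bai / fitted
    out = pd.Series(index, index=series.years, name=series.tree_id)
    out.attrs["fallback"] = used_fallback
    return out


def build_chronology(
    indexed: Mapping[str, pd.Series] | Sequence[pd.Series], group_label: str
) -> IndexChronology:
    """Year-by-year arithmetic mean of standardized series, with sample depth."""
    if isinstance(indexed, Mapping):
        frame = pd.DataFrame(dict(indexed))
    else:
        frame = pd.DataFrame({i: s for i, s in enumerate(indexed)})
    if frame.shape[1] < 1:
        raise ValidationError("need at least one standardized series")
    frame = frame.sort_index()
    return IndexChronology(
        group_label=group_label,
        years=frame.index.to_numpy(dtype=int),
        index=frame.mean(axis=1).to_numpy(),
        sample_depth=frame.notna().sum(axis=1).to_numpy(dtype=int),
    )


def pentad_start(year: int | np.ndarray) -> int | np.ndarray:
    """Start year of the calendar pentad containing ``year`` (multiples of 5)."""
    return (np.asarray(year) // 5) * 5 if isinstance(year, np.ndarray) else (year // 5) * 5


def aggregate_pentads(annual: pd.Series, min_years: int = 3) -> pd.DataFrame:
    """Average an annual series over calendar pentads [5m, 5m+4].

    Returns a frame indexed by pentad start year with columns ``mean``,
    ``n_years`` and ``complete`` (n_years >= ``min_years``).
    """
    annual = annual.dropna()
    if annual.empty:
        return pd.DataFrame(columns=["mean", "n_years", "complete"])
    starts = (annual.index.to_numpy(dtype=int) // 5) * 5
    grouped = annual.groupby(starts)
    out = pd.DataFrame({"mean": grouped.mean(), "n_years": grouped.size()})
    out["complete"] = out["n_years"] >= min_years
    out.index.name = "pentad_start_year"
    return out


def reconstruct_historical_diameter(
    tree: TreeRecord, mean_widths: pd.Series
) -> pd.Series:
    """Back-cast stem diameter (cm) from the measured diameter and ring widths.

    D(sampling_year) = measured diameter; stepping backwards,
    D(t−1) = D(t) − 2·w(t)/10 with w(t) the tree-mean ring width (mm) of year
    t.  The series is truncated (with no error) at the first year where the
    reconstruction would become nonpositive.
    """
    if tree.diameter_cm is None or tree.sampling_year is None:
        raise ValidationError(f"tree {tree.tree_id}: diameter/sampling_year unset")
    widths = mean_widths.dropna().sort_index()
    widths = widths[widths.index <= tree.sampling_year]
    if widths.empty:
        raise ValidationError(f"tree {tree.tree_id}: no widths before sampling year")
    years = [tree.sampling_year]
    diams = [float(tree.diameter_cm)]
    d = float(tree.diameter_cm)
    for year in range(tree.sampling_year, int(widths.index.min()) - 1, -1):
        d_prev = d - 2.0 * float(widths.get(year, 0.0)) / 10.0
        if d_prev <= 0:
            break
        years.append(year - 1)
        diams.append(d_prev)
        d = d_prev
    out = pd.Series(diams, index=years, name=tree.tree_id).sort_index()
    return out


def estimate_age(tree_series: Iterable[RingWidthSeries]) -> int:
    """Tree age in years = length of the longest ring-width series."""
    lengths = [len(s.widths) for s in tree_series]
    if not lengths:
        raise ValidationError("need at least one series to estimate age")
    return max(lengths)


def build_pentad_table(
    tree_bai: Mapping[str, BaiSeries],
    trees: Sequence[TreeRecord],
    mean_widths: Mapping[str, pd.Series] | None = None,
    isotopes: Sequence | None = None,
    min_years: int = 3,
) -> pd.DataFrame:
    """Assemble the per-tree pentad table used by the linear models.

    One row per (tree, pentad) with: the pentad-mean BAI; wood δ¹³C and
    Δ¹³C where measured (``isotopes`` should carry records with ``delta13c``
    already populated); ecological-memory covariates ``bai_prev`` and
    ``delta13c_prev`` (the tree's previous-pentad values, missing for a
    tree's first pentad); and ``dbh_hist``, the mean reconstructed stem
    diameter over the pentad's years.  Incomplete pentads (< ``min_years``
    contributing years) are dropped.
    """
    sex_of = {t.tree_id: t.sex for t in trees}
    tree_of = {t.tree_id: t for t in trees}
    rows = []
    for tree_id, bai in tree_bai.items():
        if tree_id not in sex_of:
            raise ValidationError(f"tree {tree_id!r} missing from metadata")
        pent = aggregate_pentads(bai.to_pandas(), min_years=min_years)
        pent = pent[pent["complete"]]
        dbh = None
        if mean_widths is not None and tree_id in mean_widths:
            dbh = reconstruct_historical_diameter(tree_of[tree_id], mean_widths[tree_id])
        for start, rec in pent.iterrows():
            dbh_hist = np.nan
            if dbh is not None:
                window = dbh.loc[(dbh.index >= start) & (dbh.index <= start + 4)]
                if len(window):
                    dbh_hist = float(window.mean())
            rows.append(
                {
                    "tree_id": tree_id,
                    "sex": sex_of[tree_id],
                    "pentad_start_year": int(start),
                    "bai_mean": float(rec["mean"]),
                    "n_years": int(rec["n_years"]),
                    "dbh_hist": dbh_hist,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["d13c"] = np.nan
    table["delta13c"] = np.nan
    if isotopes:
        iso = pd.DataFrame(
            [
                {
                    "tree_id": r.tree_id,
                    "pentad_start_year": r.pentad_start_year,
                    "d13c": r.delta_wood,
                    "delta13c": r.delta13c,
                }
                for r in isotopes
            ]
        )
        table = table.drop(columns=["d13c", "delta13c"]).merge(
            iso, on=["tree_id", "pentad_start_year"], how="left"
        )
    table = table.sort_values(["tree_id", "pentad_start_year"]).reset_index(drop=True)
    for col, prev in [("bai_mean", "bai_prev"), ("delta13c", "delta13c_prev")]:
        shifted = table.groupby("tree_id")[col].shift(1)
        gap = table.groupby("tree_id")["pentad_start_year"].diff() != 5
        table[prev] = shifted.where(~gap)
    return table
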
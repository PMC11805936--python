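"""Climate–growth correlation functions and lagged SPEI surfaces.

Two analyses relate a standardized growth chronology to climate:

* a monthly correlation function — Pearson r between the chronology and each
  of four climate variables in each of 20 month slots from April of the year
  before growth, Apr(−1), to November of the growth year, Nov(0);

* a month × lag correlation surface — Pearson r between the chronology and
  SPEI accumulated over k = 1..36 months ending at each of 16 calendar
  months from September of the previous year, Sep(−1), to December of the
  growth year.  The surface's peak (ending month, lag, r) locates the
  time scale at which water availability best explains growth — the "drought
  legacy" of the group.

"Lag k" means k-month accumulation ending at the stated month (the SPEI
scale), not a backshift of the 1-month index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .climate import ClimateTable, SpeiCube
from .errors import ValidationError
from .growth import IndexChronology

__all__ = [
    "MONTH_SLOTS",
    "SURFACE_END_MONTHS",
    "CorrelationFunctionResult",
    "LagSurface",
    "pearson_r",
    "monthly_correlation_function",
    "lagged_spei_surface",
    "surface_peak",
]

_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

#: (month number, year offset) for Apr(−1) .. Nov(0) — 20 slots
MONTH_SLOTS: list[tuple[int, int]] = [(m, -1) for m in range(4, 13)] + [
    (m, 0) for m in range(1, 12)
]

#: (month number, year offset) for Sep(−1) .. Dec(0) — 16 ending months
SURFACE_END_MONTHS: list[tuple[int, int]] = [(m, -1) for m in range(9, 13)] + [
    (m, 0) for m in range(1, 13)
]


def slot_label(month: int, offset: int) -> str:
    """Human label for a month slot, e.g. 'Sep(-1)' or 'Jun'."""
    return f"{_MONTH_ABBR[month - 1]}(-1)" if offset else _MONTH_ABBR[month - 1]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r on pairwise-complete values with a two-tailed t-test p.

    Returns (r, p, n).  Raises :class:`ValidationError` for fewer than 3
    complete pairs or zero variance in either member.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def _column_correlations(chron: np.ndarray, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson r/p of one vector against each column of ``mat`` (pairwise complete)."""
    n_cols = mat.shape[1]
    rs = np.full(n_cols, np.nan)
    ps = np.full(n_cols, np.nan)
    ns = np.zeros(n_cols, dtype=int)
    for j in range(n_cols):
        col = mat[:, j]
        ok = np.isfinite(chron) & np.isfinite(col)
        n = int(ok.sum())
        ns[j] = n
        if n < 4:
            continue
        xc = chron[ok] - chron[ok].mean()
        yc = col[ok] - col[ok].mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        if denom == 0:
            continue
        r = float(np.clip(xc @ yc / denom, -1.0, 1.0))
        rs[j] = r
        if abs(r) == 1.0:
            ps[j] = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            ps[j] = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rs, ps, ns


@dataclass
class CorrelationFunctionResult:
    """Monthly correlation function of one chronology, long format."""

    group_label: str
    table: pd.DataFrame  # variable, month, offset, slot, r, p, n, sig05, sig01, sig05_sidak

    def cell(self, variable: str, month: int, offset: int = 0) -> pd.Series:
        q = self.table
        row = q[(q["variable"] == variable) & (q["month"] == month) & (q["offset"] == offset)]
        return row.iloc[0]


def monthly_correlation_function(
    chronology: IndexChronology,
    table: ClimateTable,
    period: tuple[int, int],
    variables: Sequence[str] = ("tmed", "prec", "cld", "pet"),
) -> CorrelationFunctionResult:
    """Correlate a chronology with each climate variable in each month slot.

    A slot (m, −1) pairs the chronology value of year t with the climate of
    month m in year t−1.  Significance flags at 0.05/0.01 follow the per-cell
    convention; a Šidák-corrected 0.05 flag over the result's cells is
    emitted alongside for users who want family-wise control.
    """
    y0, y1 = period
    years = np.arange(y0, y1 + 1)
    chron = chronology.to_pandas().reindex(years).to_numpy()
    rows = []
    mats = {v: table.pivot(v) for v in variables}
    n_cells = len(variables) * len(MONTH_SLOTS)
    sidak_alpha = 1.0 - (1.0 - 0.05) ** (1.0 / n_cells)
    for variable in variables:
        pivot = mats[variable]
        cols = np.column_stack(
            [
                pivot.reindex(years + offset)[month].to_numpy()
                for month, offset in MONTH_SLOTS
            ]
        )
        rs, ps, ns = _column_correlations(chron, cols)
        for (month, offset), r, p, n in zip(MONTH_SLOTS, rs, ps, ns):
            rows.append(
                {
                    "variable": variable,
                    "month": month,
                    "offset": offset,
                    "slot": slot_label(month, offset),
                    "r": r,
                    "p": p,
                    "n": n,
                    "sig05": bool(p < 0.05) if np.isfinite(p) else False,
                    "sig01": bool(p < 0.01) if np.isfinite(p) else False,
                    "sig05_sidak": bool(p < sidak_alpha) if np.isfinite(p) else False,
                }
            )
    return CorrelationFunctionResult(chronology.group_label, pd.DataFrame(rows))


@dataclass
class LagSurface:
    """Month × lag Pearson-correlation surface of a chronology with SPEI.

    ``r`` and ``n`` are (16 ending months × lags) frames indexed by slot
    label, columns = accumulation lag in months.
    """

    group_label: str
    r: pd.DataFrame
    n: pd.DataFrame

    @property
    def peak(self) -> tuple[str, int, float]:
        return surface_peak(self)


def lagged_spei_surface(
    chronology: IndexChronology,
    cube: SpeiCube,
    period: tuple[int, int],
) -> LagSurface:
    """Correlate a chronology with SPEI at every (ending month, lag) cell.

    Cell (m, k) uses SPEI of scale k ending at calendar month m — of the
    previous year for the Sep(−1)..Dec(−1) rows.  Undefined cube cells
    propagate as NaN.
    """
    y0, y1 = period
    years = np.arange(y0, y1 + 1)
    chron = chronology.to_pandas().reindex(years).to_numpy()
    lags = [int(k) for k in cube.scales]
    labels = [slot_label(m, off) for m, off in SURFACE_END_MONTHS]
    r_mat = np.full((len(SURFACE_END_MONTHS), len(lags)), np.nan)
    n_mat = np.zeros_like(r_mat, dtype=int)
    year_pos = {int(y): i for i, y in enumerate(cube.years)}
    for si, (month, offset) in enumerate(SURFACE_END_MONTHS):
        idx = np.array([year_pos.get(int(y) + offset, -1) for y in years])
        valid = idx >= 0
        cols = np.full((len(years), len(lags)), np.nan)
        cols[valid] = cube.values[:, idx[valid], month - 1].T
        rs, _, ns = _column_correlations(chron, cols)
        r_mat[si] = rs
        n_mat[si] = ns
    return LagSurface(
        group_label=chronology.group_label,
        r=pd.DataFrame(r_mat, index=labels, columns=lags),
        n=pd.DataFrame(n_mat, index=labels, columns=lags),
    )


def surface_peak(surface: LagSurface) -> tuple[str, int, float]:
    """(ending month, lag, r) of the maximum correlation.

    Ties break toward the smaller lag, then the earlier ending month.
    """
    r = surface.r.to_numpy()
    if not np.isfinite(r).any():
        raise ValidationError("surface has no defined cells")
    best = np.nanmax(r)
    # scan lags outer, months inner so the first hit honours the tie rule
    for lag_j in range(r.shape[1]):
        for month_i in range(r.shape[0]):
            if np.isfinite(r[month_i, lag_j]) and r[month_i, lag_j] == best:
                return (
                    str(surface.r.index[month_i]),
                    int(surface.r.columns[lag_j]),
                    float(best),
                )
    raise AssertionError("unreachable")
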
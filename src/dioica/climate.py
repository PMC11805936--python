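"""Monthly climate ingestion, water balance and multi-scale SPEI.

The standardized precipitation–evapotranspiration index (SPEI) standardizes
the climatic water balance D = P − PET accumulated over k months.  For each
(accumulation scale k, calendar month) cell, the k-month sums over the
calibration years are fitted with a three-parameter log-logistic
distribution,

    F(x) = [1 + (α/(x − γ))^β]^(−1),

estimated by unbiased probability-weighted moments, and each value is mapped
through Φ⁻¹(F(x)) to a standard-normal deviate.  Negative SPEI means drier
than the calibration climatology, positive wetter; by construction each
calibration cell has mean ≈ 0 and s.d. ≈ 1.

A Thornthwaite (1948) monthly PET routine is provided for tables lacking a
PET column.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import norm

from .errors import CoverageError, FitError, ValidationError

__all__ = [
    "ClimateTable",
    "SpeiCube",
    "read_climate",
    "write_climate",
    "thornthwaite_pet",
    "water_balance",
    "aggregate_scale",
    "fit_loglogistic_pwm",
    "loglogistic_cdf",
    "loglogistic_ppf",
    "spei_transform",
    "build_spei_cube",
    "PROB_CLAMP",
]

#: probability clamp before the normal quantile; bounds |SPEI| at ~4.75
PROB_CLAMP = 1e-6

_CLIMATE_COLS = ["year", "month", "tmed", "prec", "cld", "pet"]
_DAYS_IN_MONTH = np.array([calendar.monthrange(2001, m)[1] for m in range(1, 13)])


@dataclass
class ClimateTable:
    """Monthly climate: mean temperature °C, precipitation mm, cloud cover %
    and potential evapotranspiration mm, one row per (year, month)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = set(_CLIMATE_COLS[:5]) - set(df.columns)
        if missing:
            raise ValidationError(f"climate table missing columns: {sorted(missing)}")
        if "pet" not in df.columns:
            df["pet"] = np.nan
        if df.duplicated(subset=["year", "month"]).any():
            dup = df[df.duplicated(subset=["year", "month"])][["year", "month"]]
            raise ValidationError(
                f"duplicate (year, month) rows: {dup.to_records(index=False).tolist()}"
            )
        if not df["month"].between(1, 12).all():
            raise ValidationError("month must be in 1..12")
        if (df["prec"] < 0).any():
            raise ValidationError("precipitation must be >= 0")
        if not df["cld"].between(0, 100).all():
            raise ValidationError("cloud cover must be in [0, 100]")
        self.data = df.sort_values(["year", "month"]).reset_index(drop=True)

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    def gaps(self) -> list[tuple[int, int]]:
        """Missing (year, month) pairs within the table's year span."""
        have = set(zip(self.data["year"], self.data["month"]))
        y0, y1 = int(self.data["year"].min()), int(self.data["year"].max())
        return [
            (y, m)
            for y in range(y0, y1 + 1)
            for m in range(1, 13)
            if (y, m) not in have
        ]

    def monthly(self, variable: str) -> pd.Series:
        """The variable as a series indexed by (year, month)."""
        return self.data.set_index(["year", "month"])[variable]

    def pivot(self, variable: str) -> pd.DataFrame:
        """Year × month matrix of one variable."""
        return self.data.pivot(index="year", columns="month", values=variable)


def read_climate(path: str | Path) -> ClimateTable:
    """Read the climate CSV (year, month, tmed, prec, cld[, pet])."""
    df = pd.read_csv(path)
    return ClimateTable(df)


def write_climate(table: ClimateTable, path: str | Path) -> Path:
    path = Path(path)
    table.data[_CLIMATE_COLS].to_csv(path, index=False, float_format="%.6g")
    return path


def _day_length_hours(latitude_deg: float, months: np.ndarray) -> np.ndarray:
    """Mean day length (h) per month from standard solar declination."""
    mid_doy = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])
    decl = 0.4093 * np.sin(2 * np.pi * (284 + mid_doy[months - 1]) / 365.0)
    phi = math.radians(latitude_deg)
    cos_ws = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    return 24.0 / np.pi * ws


def thornthwaite_pet(
    tmed: pd.Series, latitude_deg: float
) -> pd.Series:
    """Thornthwaite (1948) monthly potential evapotranspiration, mm.

    ``tmed`` is indexed by (year, month).  Annual heat index
    I = Σ_m (max(T̄_m, 0)/5)^1.514 over the 12 long-run monthly means; the
    exponent a is the standard cubic in I; each month's raw PET
    16·(10·T/I)^a is corrected by day length (N/12) and month length (d/30).
    Months at or below 0 °C evaporate nothing.
    """
    if abs(latitude_deg) >= 66.5:
        raise ValidationError("latitude must be below the polar circles")
    if len(tmed) < 12:
        raise ValidationError("need >= 12 months of temperature")
    idx = pd.MultiIndex.from_tuples(tmed.index, names=["year", "month"])
    t = pd.Series(tmed.to_numpy(dtype=float), index=idx)
    monthly_means = t.groupby(level="month").mean()
    heat = float(((monthly_means.clip(lower=0.0) / 5.0) ** 1.514).sum())
    if heat == 0:
        return pd.Series(0.0, index=t.index, name="pet")
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    months = idx.get_level_values("month").to_numpy()
    temp = t.to_numpy()
    raw = np.where(temp > 0, 16.0 * (10.0 * np.clip(temp, 0, None) / heat) ** a, 0.0)
    n_hours = _day_length_hours(latitude_deg, months)
    days = _DAYS_IN_MONTH[months - 1]
    pet = raw * (n_hours / 12.0) * (days / 30.0)
    return pd.Series(pet, index=t.index, name="pet")


def water_balance(table: ClimateTable) -> pd.Series:
    """Monthly climatic water balance D = prec − pet (mm), (year, month)-indexed."""
    df = table.data
    if df["pet"].isna().any():
        raise ValidationError("pet column incomplete; run thornthwaite_pet first")
    d = df["prec"].to_numpy() - df["pet"].to_numpy()
    idx = pd.MultiIndex.from_arrays([df["year"], df["month"]], names=["year", "month"])
    return pd.Series(d, index=idx, name="water_balance")


def aggregate_scale(d: pd.Series | np.ndarray, k: int) -> np.ndarray:
    """Backward k-month rolling sums; the first k−1 positions are NaN."""
    values = np.asarray(d, dtype=float)
    if k < 1:
        raise ValidationError("scale k must be >= 1")
    if k > len(values):
        raise CoverageError(f"scale {k} exceeds series length {len(values)}")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = np.full(len(values), np.nan)
    out[k - 1 :] = csum[k:] - csum[:-k]
    return out


def _pwm(sample: np.ndarray) -> tuple[float, float, float]:
    """Unbiased probability-weighted moments w0, w1, w2 of a sample."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    i = np.arange(1, n + 1)
    w0 = x.mean()
    w1 = float(np.sum((n - i) / (n - 1) * x) / n)
    w2 = float(np.sum((n - i) * (n - i - 1) / ((n - 1) * (n - 2)) * x) / n)
    return float(w0), w1, w2


def fit_loglogistic_pwm(sample: Sequence[float]) -> tuple[float, float, float]:
    """Fit the 3-parameter log-logistic by unbiased PWMs.

    Returns (alpha, beta, gamma) of F(x) = [1 + (α/(x−γ))^β]^(−1).  Requires
    n ≥ 10, a non-degenerate sample, and β > 1 (finite mean); otherwise a
    :class:`FitError` is raised and the caller should mark the cell undefined.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 10:
        raise FitError(f"need >= 10 values to fit, got {len(x)}")
    if np.ptp(x) == 0:
        raise FitError("degenerate sample (all values equal)")
    w0, w1, w2 = _pwm(x)
    denom = 6.0 * w1 - w0 - 6.0 * w2
    if denom == 0:
        raise FitError("PWM ratio undefined")
    beta = (2.0 * w1 - w0) / denom
    if not np.isfinite(beta) or beta <= 1.0:
        raise FitError(f"beta estimate {beta:.4g} <= 1 (infinite mean)")
    g1g2 = gamma_fn(1.0 + 1.0 / beta) * gamma_fn(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g1g2
    gamma = w0 - alpha * g1g2
    if not (np.isfinite(alpha) and np.isfinite(gamma)) or alpha <= 0:
        raise FitError("nonfinite or nonpositive scale parameter")
    return float(alpha), float(beta), float(gamma)


def loglogistic_cdf(x, alpha: float, beta: float, gamma: float):
    """CDF of the 3-parameter log-logistic; 0 at and below the location γ."""
    x = np.asarray(x, dtype=float)
    z = x - gamma
    with np.errstate(divide="ignore", over="ignore"):
        p = np.where(z > 0, 1.0 / (1.0 + (alpha / np.where(z > 0, z, 1.0)) ** beta), 0.0)
    return float(p) if p.ndim == 0 else p


def loglogistic_ppf(p, alpha: float, beta: float, gamma: float):
    """Quantile function; used for inverse-CDF sampling in tests."""
    p = np.asarray(p, dtype=float)
    x = gamma + alpha * (p / (1.0 - p)) ** (1.0 / beta)
    return float(x) if x.ndim == 0 else x


def spei_transform(x, params: tuple[float, float, float]):
    """Map aggregated water-balance values through F then Φ⁻¹.

    Probabilities are clamped to [1e−6, 1−1e−6] so extreme indices are
    bounded at |SPEI| ≈ 4.75.
    """
    alpha, beta, gamma = params
    p = np.clip(loglogistic_cdf(x, alpha, beta, gamma), PROB_CLAMP, 1.0 - PROB_CLAMP)
    out = norm.ppf(p)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class SpeiCube:
    """SPEI values indexed by (aggregation scale, year, calendar month).

    ``values`` has shape (len(scales), len(years), 12); NaN marks cells where
    the k-month window is not covered or the distribution fit failed (those
    fits are listed in ``fit_failures``).
    """

    scales: np.ndarray
    years: np.ndarray
    values: np.ndarray
    calibration: tuple[int, int]
    fit_failures: list[tuple[int, int, str]] = field(default_factory=list)

    def sel(self, scale: int, month: int) -> pd.Series:
        """SPEI at one (scale, month) as a year-indexed series."""
        k = int(np.where(self.scales == scale)[0][0])
        return pd.Series(self.values[k, :, month - 1], index=self.years)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (scale, year, month, spei) frame, defined cells only."""
        ks, ys, ms = np.meshgrid(
            self.scales, self.years, np.arange(1, 13), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "scale": ks.ravel(),
                "year": ys.ravel(),
                "month": ms.ravel(),
                "spei": self.values.ravel(),
            }
        )
        return df.dropna(subset=["spei"]).reset_index(drop=True)


def build_spei_cube(
    table: ClimateTable,
    scales: Sequence[int] = range(1, 37),
    calibration_period: tuple[int, int] | None = None,
) -> SpeiCube:
    """Fit-and-transform SPEI for every scale and calendar month.

    For each scale k the water balance is summed over backward k-month
    windows on the continuous monthly series; for each calendar month the
    log-logistic is fitted on the calibration years and applied to all
    years.  Cells whose fit fails stay NaN and are listed in the cube's
    ``fit_failures`` manifest.
    """
    d = water_balance(table)
    years = table.years
    if np.any(np.diff(years) != 1):
        raise ValidationError("climate years must be contiguous")
    if table.gaps():
        raise ValidationError(f"climate table has gaps: {table.gaps()[:5]}")
    if calibration_period is None:
        calibration_period = (int(years.min()), int(years.max()))
    c0, c1 = calibration_period
    scales = np.asarray(list(scales), dtype=int)
    n_years = len(years)
    values = np.full((len(scales), n_years, 12), np.nan)
    failures: list[tuple[int, int, str]] = []
    d_flat = d.to_numpy()  # sorted by (year, month)
    cal_mask = (years >= c0) & (years <= c1)
    for ki, k in enumerate(scales):
        agg = aggregate_scale(d_flat, int(k)).reshape(n_years, 12)
        for m in range(12):
            col = agg[:, m]
            sample = col[cal_mask & np.isfinite(col)]
            try:
                params = fit_loglogistic_pwm(sample)
            except FitError as exc:
                failures.append((int(k), m + 1, str(exc)))
                continue
            defined = np.isfinite(col)
            values[ki, defined, m] = spei_transform(col[defined], params)
    return SpeiCube(
        scales=scales,
        years=years,
        values=values,
        calibration=(c0, c1),
        fit_failures=failures,
    )
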
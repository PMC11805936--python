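"""Synthetic study generator: climate, ring widths, metadata and isotopes.

The generator emulates a temperate-mountain dioecious-tree study so every
pipeline stage can be exercised and validated without field data:

* monthly climate with a seasonal cycle, a linear warming trend and AR(1)
  noise, tuned so long-run means land near 938 mm yr⁻¹ precipitation and
  9 °C mean temperature, with cloud cover anticorrelated with temperature
  and PET from the Thornthwaite formula;
* per-sex tree cohorts whose log basal-area increment responds linearly to
  standardized climate and multi-month SPEI predictors (the implanted
  sensitivities are the recovery targets of the downstream correlation and
  model-selection analyses), with a shared stand-level AR(1) disturbance
  and individual AR(1) noise; ring widths are recovered by inverting the
  BAI recursion and measured with per-core noise;
* pentad wood isotopes whose discrimination Δ¹³C carries a sex offset and a
  negative coupling to standardized pentad growth, back-solved to δ¹³C_wood
  through a declining atmospheric δ¹³C_air reference.

Every true coefficient is recorded in a truth ledger so tests can check
end-to-end parameter recovery.  Fixed seed ⇒ byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .climate import ClimateTable, build_spei_cube, thornthwaite_pet
from .errors import GenerationError, ValidationError
from .growth import BaiSeries, aggregate_pentads
from .isotope import AirDeltaSeries, WoodIsotopeRecord, air_delta_for_pentad, solve_delta_wood
from .ringdata import RingWidthSeries, TreeRecord

__all__ = [
    "Sensitivity",
    "ScenarioConfig",
    "generate_climate",
    "generate_trees",
    "generate_isotopes",
]

# monthly climatology defaults (Jan..Dec) for a wet temperate mountain site
_TMED_CLIM = [1.5, 2.2, 4.7, 7.2, 10.7, 14.5, 17.2, 17.0, 14.2, 10.2, 5.7, 2.7]
_PREC_CLIM = [110.0, 95.0, 85.0, 75.0, 70.0, 50.0, 30.0, 35.0, 65.0, 95.0, 115.0, 113.0]
_CLD_CLIM = [70.0, 66.0, 62.0, 58.0, 56.0, 50.0, 42.0, 44.0, 52.0, 62.0, 68.0, 72.0]


@dataclass(frozen=True)
class Sensitivity:
    """One implanted climate sensitivity of log-BAI.

    ``variable`` is a climate column (tmed, prec, cld, pet) or ``spei``;
    for SPEI, ``scale`` is the accumulation length in months.  ``offset``
    is the year offset of the month relative to the growth year (0 current,
    −1 previous).  ``coef`` multiplies the standardized predictor.
    """

    variable: str
    month: int
    coef: float
    offset: int = 0
    scale: int | None = None


def _default_male_sens() -> tuple[Sensitivity, ...]:
    return (
        Sensitivity("spei", month=1, coef=0.18, offset=0, scale=10),
        Sensitivity("tmed", month=6, coef=0.07, offset=0),
        Sensitivity("cld", month=6, coef=-0.06, offset=0),
        Sensitivity("tmed", month=9, coef=-0.06, offset=-1),
    )


def _default_female_sens() -> tuple[Sensitivity, ...]:
    return (
        Sensitivity("spei", month=10, coef=0.18, offset=0, scale=30),
        Sensitivity("cld", month=5, coef=0.06, offset=-1),
        Sensitivity("cld", month=6, coef=0.06, offset=-1),
        Sensitivity("tmed", month=8, coef=-0.05, offset=-1),
        Sensitivity("tmed", month=9, coef=-0.05, offset=-1),
    )


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    years: tuple[int, int] = (1900, 2001)
    n_male: int = 16
    n_female: int = 14
    seed: int = 0
    latitude_deg: float = 42.8
    sampling_year: int = 2002

    # climate
    tmed_climatology: tuple[float, ...] = tuple(_TMED_CLIM)
    prec_climatology: tuple[float, ...] = tuple(_PREC_CLIM)
    cld_climatology: tuple[float, ...] = tuple(_CLD_CLIM)
    warming_trend_c_per_century: float = 1.0
    tmed_noise_sd: float = 1.2
    prec_noise_frac: float = 0.45
    cld_noise_sd: float = 5.0
    cld_tmed_slope: float = -2.2  # % cover per °C anomaly
    climate_ar1: float = 0.3

    # growth
    bai_base_male: float = 1.75
    bai_base_female: float = 1.40
    age_trend_per_year: float = 0.012
    male_sensitivities: tuple[Sensitivity, ...] = field(default_factory=_default_male_sens)
    female_sensitivities: tuple[Sensitivity, ...] = field(default_factory=_default_female_sens)
    stand_noise_sd: float = 0.28
    indiv_noise_sd: float = 0.35
    growth_ar1: float = 0.3
    age_range_male: tuple[int, int] = (37, 140)
    age_range_female: tuple[int, int] = (54, 142)
    cores_per_tree: tuple[int, int] = (2, 3)
    core_noise_sd_mm: float = 0.05
    bark_allowance_cm: float = 0.8

    # isotopes
    delta13c_mean_male: float = 17.51
    delta13c_mean_female: float = 18.15
    isotope_coupling: float = -0.40  # ‰ of Δ13C per s.d. of pentad BAI
    isotope_noise_sd: float = 0.11
    air_start_permil: float = -6.4
    air_end_permil: float = -8.0

    def __post_init__(self) -> None:
        if self.n_male < 1 or self.n_female < 1:
            raise ValidationError("tree counts must be >= 1")
        for name in ("tmed_noise_sd", "cld_noise_sd", "indiv_noise_sd",
                     "stand_noise_sd", "core_noise_sd_mm", "isotope_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        self.male_sensitivities = tuple(
            s if isinstance(s, Sensitivity) else Sensitivity(**s)
            for s in self.male_sensitivities
        )
        self.female_sensitivities = tuple(
            s if isinstance(s, Sensitivity) else Sensitivity(**s)
            for s in self.female_sensitivities
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError("scenario YAML must contain a mapping")
        for key in ("years", "age_range_male", "age_range_female", "cores_per_tree"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("tmed_climatology", "prec_climatology", "cld_climatology"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("male_sensitivities", "female_sensitivities"):
            if key in raw:
                raw[key] = tuple(
                    Sensitivity(**s) if isinstance(s, dict) else s for s in raw[key]
                )
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**raw)


def _rng(config: ScenarioConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def generate_climate(config: ScenarioConfig) -> ClimateTable:
    """Monthly climate table over the scenario years (PET via Thornthwaite)."""
    y0, y1 = config.years
    if y1 - y0 + 1 < 40:
        raise ValidationError("scenario needs >= 40 years of climate")
    rng = _rng(config, stage=0)
    years = np.arange(y0, y1 + 1)
    n = len(years) * 12
    yy = np.repeat(years, 12)
    mm = np.tile(np.arange(1, 13), len(years))
    trend = config.warming_trend_c_per_century * (yy - y0) / 100.0
    t_noise = _ar1(rng, n, config.climate_ar1, config.tmed_noise_sd)
    tmed = np.asarray(config.tmed_climatology)[mm - 1] + trend + t_noise
    # monthly precipitation is right-skewed; gamma keeps it nonnegative with
    # coefficient of variation prec_noise_frac
    prec_mu = np.asarray(config.prec_climatology)[mm - 1]
    if config.prec_noise_frac > 0:
        shape = 1.0 / config.prec_noise_frac**2
        prec = rng.gamma(shape, prec_mu / shape, n)
    else:
        prec = prec_mu.astype(float)
    cld = np.clip(
        np.asarray(config.cld_climatology)[mm - 1]
        + config.cld_tmed_slope * t_noise
        + rng.normal(0.0, config.cld_noise_sd, n),
        0.0,
        100.0,
    )
    df = pd.DataFrame({"year": yy, "month": mm, "tmed": tmed, "prec": prec, "cld": cld})
    idx = pd.MultiIndex.from_arrays([yy, mm], names=["year", "month"])
    df["pet"] = thornthwaite_pet(pd.Series(tmed, index=idx), config.latitude_deg).to_numpy()
    return ClimateTable(df)


def _predictor_series(
    sens: Sensitivity, climate: ClimateTable, cube, years: np.ndarray
) -> np.ndarray:
    """Standardized predictor value per growth year (NaN outside coverage -> 0)."""
    if sens.variable == "spei":
        series = cube.sel(int(sens.scale), sens.month)
    else:
        series = climate.pivot(sens.variable)[sens.month]
    vals = series.reindex(years + sens.offset).to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        return np.zeros_like(vals)
    mu = vals[finite].mean()
    sd = vals[finite].std()
    z = (vals - mu) / sd if sd > 0 else np.zeros_like(vals)
    return np.nan_to_num(z, nan=0.0)


def generate_trees(
    config: ScenarioConfig, climate: ClimateTable
) -> tuple[list[TreeRecord], list[RingWidthSeries], dict]:
    """Simulate per-tree BAI from implanted sensitivities; invert to widths.

    log BAI_t = log(base_sex·(1 + age_slope·age_t)) + Σ coef·z_t + stand
    AR(1) + individual AR(1); widths follow from
    w_t = 10·(√(r_{t−1}² + BAI_t/π) − r_{t−1}) mm, and each core re-measures
    the tree's widths with independent noise (floored at 0).  Returns the
    metadata records, all core series, and a truth ledger of every implanted
    coefficient.
    """
    rng = _rng(config, stage=1)
    y0, y1 = config.years
    last_ring_year = min(config.sampling_year - 1, y1)
    needed_scales = sorted(
        {int(s.scale) for s in (*config.male_sensitivities, *config.female_sensitivities)
         if s.variable == "spei"}
    )
    cube = build_spei_cube(climate, scales=needed_scales or [1])
    all_years = np.arange(y0, last_ring_year + 1)
    stand = _ar1(rng, len(all_years), config.growth_ar1, config.stand_noise_sd)
    stand_by_year = dict(zip(all_years, stand))

    signals = {}
    for sex, sens_list in (("male", config.male_sensitivities),
                           ("female", config.female_sensitivities)):
        z = np.zeros(len(all_years))
        for s in sens_list:
            z += s.coef * _predictor_series(s, climate, cube, all_years)
        signals[sex] = dict(zip(all_years, z))

    records: list[TreeRecord] = []
    series: list[RingWidthSeries] = []
    truth: dict = {
        "seed": config.seed,
        "trees": {},
        "sensitivities": {
            sex: [dataclasses.asdict(s) for s in sens]
            for sex, sens in (("male", config.male_sensitivities),
                              ("female", config.female_sensitivities))
        },
        "bai_base": {"male": config.bai_base_male, "female": config.bai_base_female},
        "age_trend_per_year": config.age_trend_per_year,
        "noise": {"stand_sd": config.stand_noise_sd, "indiv_sd": config.indiv_noise_sd,
                  "ar1": config.growth_ar1},
    }
    counters = {"male": 0, "female": 0}
    cohorts = [("male", config.n_male, config.bai_base_male, config.age_range_male),
               ("female", config.n_female, config.bai_base_female, config.age_range_female)]
    for sex, n_trees, base, age_range in cohorts:
        for _ in range(n_trees):
            counters[sex] += 1
            tree_id = f"{sex[0].upper()}{counters[sex]:02d}"
            age = int(rng.integers(age_range[0], age_range[1] + 1))
            first_year = last_ring_year - age + 1
            t_years = np.arange(first_year, last_ring_year + 1)
            ages = t_years - first_year + 1
            indiv = _ar1(rng, len(t_years), config.growth_ar1, config.indiv_noise_sd)
            log_bai = (
                np.log(base * (1.0 + config.age_trend_per_year * ages))
                + np.array([signals[sex].get(int(y), 0.0) for y in t_years])
                + np.array([stand_by_year.get(int(y), 0.0) for y in t_years])
                + indiv
            )
            bai = np.exp(log_bai)
            # invert the BAI recursion to ring widths (mm)
            r = 0.0
            widths = np.empty(len(bai))
            for i, b in enumerate(bai):
                r_next = np.sqrt(r**2 + b / np.pi)
                widths[i] = 10.0 * (r_next - r)
                r = r_next
            if not np.all(np.isfinite(widths)):
                raise GenerationError(f"tree {tree_id}: nonfinite widths")
            n_cores = int(rng.integers(config.cores_per_tree[0], config.cores_per_tree[1] + 1))
            for ci in range(n_cores):
                noisy = widths + rng.normal(0.0, config.core_noise_sd_mm, len(widths))
                noisy = np.clip(np.round(noisy, 2), 0.0, None)
                series.append(
                    RingWidthSeries(
                        series_id=f"{tree_id}{'abc'[ci]}",
                        tree_id=tree_id,
                        first_year=int(first_year),
                        widths=noisy,
                    )
                )
            diameter = 2.0 * r + config.bark_allowance_cm
            records.append(
                TreeRecord(
                    tree_id=tree_id,
                    sex=sex,
                    diameter_cm=round(float(diameter), 1),
                    sampling_year=config.sampling_year,
                )
            )
            truth["trees"][tree_id] = {
                "sex": sex,
                "age": age,
                "first_year": int(first_year),
                "n_cores": n_cores,
                "true_bai": [float(b) for b in bai],
            }
    return records, series, truth


def generate_isotopes(
    config: ScenarioConfig,
    tree_bai: Mapping[str, BaiSeries],
    trees: Sequence[TreeRecord],
) -> tuple[list[WoodIsotopeRecord], AirDeltaSeries, dict]:
    """Pentad wood isotopes coupled to growth, plus the air reference.

    Discrimination is generated directly: Δ¹³C(tree, pentad) = sex mean +
    coupling·z(pentad BAI, standardized within sex) + noise, then δ¹³C_wood
    is back-solved through the discrimination identity against the pentad
    mean of the declining δ¹³C_air series.  Negative coupling therefore
    yields a negative BAI~Δ¹³C regression slope by construction.
    """
    rng = _rng(config, stage=2)
    y0, y1 = config.years
    air_years = np.arange(y0, y1 + 1)
    span = max(2000 - y0, 1)
    air_vals = config.air_start_permil + (
        (config.air_end_permil - config.air_start_permil) * (air_years - y0) / span
    )
    air = AirDeltaSeries(air_years, air_vals)
    sex_of = {t.tree_id: t.sex for t in trees}
    sex_mean = {"male": config.delta13c_mean_male, "female": config.delta13c_mean_female}

    pent_rows = []
    for tree_id, bai in tree_bai.items():
        pent = aggregate_pentads(bai.to_pandas())
        pent = pent[pent["complete"]]
        for start, rec in pent.iterrows():
            if start < y0 or start + 4 > y1:
                continue
            pent_rows.append((tree_id, sex_of[tree_id], int(start), float(rec["mean"])))
    frame = pd.DataFrame(pent_rows, columns=["tree_id", "sex", "pentad", "bai"])
    records: list[WoodIsotopeRecord] = []
    for sex, sub in frame.groupby("sex", sort=True):
        z = (sub["bai"] - sub["bai"].mean()) / (sub["bai"].std(ddof=0) or 1.0)
        noise = rng.normal(0.0, config.isotope_noise_sd, len(sub))
        deltas = sex_mean[sex] + config.isotope_coupling * z.to_numpy() + noise
        for (_, row), d13 in zip(sub.iterrows(), deltas):
            d_air = air_delta_for_pentad(air, int(row["pentad"]))
            records.append(
                WoodIsotopeRecord(
                    tree_id=row["tree_id"],
                    pentad_start_year=int(row["pentad"]),
                    delta_wood=float(solve_delta_wood(d13, d_air)),
                )
            )
    records.sort(key=lambda r: (r.tree_id, r.pentad_start_year))
    truth = {
        "delta13c_mean": sex_mean,
        "coupling": config.isotope_coupling,
        "noise_sd": config.isotope_noise_sd,
        "air": {"start": config.air_start_permil, "end": config.air_end_permil},
    }
    return records, air, truth
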
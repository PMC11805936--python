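"""Ring-width and tree-metadata I/O plus basic dating-quality checks.

Ring widths travel in the Tucson ("RWL") decadal format used by the ITRDB:
each line carries a series id, the calendar year of the first value on the
line, and up to ten integer widths; a series ends with a stop marker whose
value encodes the measurement unit (999 for 0.01 mm, -9999 for 0.001 mm).
Tree metadata is a plain CSV with columns tree_id, sex, diameter_cm,
sampling_year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DatingError, ParseError, QCError, ValidationError

__all__ = [
    "RingWidthSeries",
    "TreeRecord",
    "read_rwl",
    "write_rwl",
    "read_tree_metadata",
    "write_tree_metadata",
    "interseries_correlation",
]

#: stop-marker value -> width unit in millimetres
_STOP_UNITS = {999: 0.01, -9999: 0.001}


@dataclass
class RingWidthSeries:
    """One dated core: annual ring widths in mm from ``first_year`` onward.

    Years are implied contiguous: value ``i`` belongs to calendar year
    ``first_year + i``.  Missing rings must be encoded as width 0, never as
    gaps.
    """

    series_id: str
    tree_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size < 1:
            raise ValidationError(f"series {self.series_id}: need >= 1 width")
        if np.any(self.widths < 0):
            raise ValidationError(f"series {self.series_id}: negative width")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.widths, index=self.years, name=self.series_id)


@dataclass
class TreeRecord:
    """Metadata for one tree: id, sex, stem diameter and sampling year."""

    tree_id: str
    sex: str
    diameter_cm: float
    sampling_year: int
    age_years: int | None = field(default=None)

    def __post_init__(self) -> None:
        sex = str(self.sex).strip().lower()
        if sex not in ("male", "female"):
            raise ValidationError(
                f"tree {self.tree_id}: sex must be 'male' or 'female' "
                f"(got {self.sex!r}); abbreviations are rejected"
            )
        self.sex = sex
        if self.diameter_cm is None or not np.isfinite(self.diameter_cm):
            raise ValidationError(f"tree {self.tree_id}: missing diameter")
        if self.diameter_cm <= 0:
            raise ValidationError(f"tree {self.tree_id}: diameter must be > 0")


def _default_tree_id(series_id: str) -> str:
    """Tree id = series id minus a trailing core letter (A1a -> A1)."""
    return series_id[:-1] if len(series_id) > 1 and series_id[-1].isalpha() else series_id


def read_rwl(path: str | Path) -> list[RingWidthSeries]:
    """Parse a Tucson/RWL decadal file into :class:`RingWidthSeries`.

    Both common dialects are accepted: stop marker 999 (values in 0.01 mm)
    and -9999 (values in 0.001 mm).  Raises :class:`ParseError` naming the
    line for malformed input and :class:`DatingError` for duplicate years or
    non-contiguous decade lines.
    """
    path = Path(path)
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    closed: dict[str, int] = {}  # series -> stop marker
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) < 3:
            raise ParseError(f"{path.name}:{lineno}: expected id, year and values")
        sid = tokens[0]
        try:
            year = int(tokens[1])
            values = [int(t) for t in tokens[2:]]
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: non-integer field ({exc})") from None
        if sid in closed:
            raise ParseError(f"{path.name}:{lineno}: data after stop marker for {sid!r}")
        if values and values[-1] in _STOP_UNITS:
            closed[sid] = values[-1]
            values = values[:-1]
        raw.setdefault(sid, []).append((year, values))

    out: list[RingWidthSeries] = []
    for sid, chunks in raw.items():
        if sid not in closed:
            raise ParseError(f"{path.name}: series {sid!r} has no stop marker")
        unit = _STOP_UNITS[closed[sid]]
        expected = None
        years: list[int] = []
        widths: list[float] = []
        for year, values in chunks:
            if expected is not None and year != expected:
                raise DatingError(
                    f"series {sid!r}: decade line starts at {year}, expected {expected}"
                )
            for i, v in enumerate(values):
                y = year + i
                if y in years:
                    raise DatingError(f"series {sid!r}: duplicate year {y}")
                years.append(y)
                widths.append(v * unit)
            expected = year + len(values)
            # subsequent lines must resume exactly where this one stopped;
            # a full decadal line stops at a multiple of 10
        if not widths:
            raise ParseError(f"{path.name}: series {sid!r} is empty")
        out.append(
            RingWidthSeries(
                series_id=sid,
                tree_id=_default_tree_id(sid),
                first_year=years[0],
                widths=np.array(widths),
            )
        )
    return out


def write_rwl(series: Iterable[RingWidthSeries], path: str | Path) -> Path:
    """Write series in Tucson decadal layout (999 marker, 0.01 mm units).

    The output round-trips through :func:`read_rwl` with equality up to the
    0.01 mm quantisation of the format.
    """
    path = Path(path)
    lines: list[str] = []
    for s in series:
        if np.any(s.widths < 0):
            raise ValidationError(f"series {s.series_id}: negative width")
        values = np.rint(np.asarray(s.widths) * 100).astype(int)
        year = s.first_year
        i = 0
        while i < len(values):
            # each line runs to the end of the calendar decade
            n = min(10 - (year % 10), len(values) - i)
            chunk = values[i : i + n].tolist()
            i += n
            if i == len(values):
                chunk.append(999)
            lines.append(f"{s.series_id:<8}{year:>4d}" + "".join(f"{v:>6d}" for v in chunk))
            year += n
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path


def read_tree_metadata(path: str | Path) -> list[TreeRecord]:
    """Read the tree-metadata CSV (tree_id, sex, diameter_cm, sampling_year)."""
    df = pd.read_csv(path)
    required = {"tree_id", "sex", "diameter_cm", "sampling_year"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if df["tree_id"].duplicated().any():
        dupes = df.loc[df["tree_id"].duplicated(), "tree_id"].tolist()
        raise ValidationError(f"duplicate tree_id values: {dupes}")
    records = []
    for row in df.itertuples(index=False):
        diameter = float(row.diameter_cm) if pd.notna(row.diameter_cm) else None
        records.append(
            TreeRecord(
                tree_id=str(row.tree_id),
                sex=str(row.sex),
                diameter_cm=diameter,
                sampling_year=int(row.sampling_year),
            )
        )
    return records


def write_tree_metadata(records: Iterable[TreeRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "tree_id": r.tree_id,
                "sex": r.sex,
                "diameter_cm": r.diameter_cm,
                "sampling_year": r.sampling_year,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)
    return path


def interseries_correlation(
    series: Sequence[RingWidthSeries], min_overlap: int = 10
) -> pd.Series:
    """Pearson r of each series against the leave-one-out mean of the rest.

    Computed over the common period of all series — a lightweight surrogate
    for a full segment-shifted cross-dating check.  Adding a constant to
    every series leaves the result unchanged.
    """
    if len(series) < 2:
        raise QCError("need at least 2 series for inter-series correlation")
    frame = pd.DataFrame({s.series_id: s.to_pandas() for s in series})
    common = frame.dropna()
    if len(common) < min_overlap:
        raise QCError(
            f"common period has {len(common)} years; need >= {min_overlap}"
        )
    out = {}
    for sid in common.columns:
        others = common.drop(columns=sid).mean(axis=1)
        x = common[sid].to_numpy()
        y = others.to_numpy()
        sx, sy = np.std(x), np.std(y)
        if sx == 0 or sy == 0:
            raise QCError(f"series {sid!r}: zero variance over common period")
        out[sid] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="interseries_r")
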
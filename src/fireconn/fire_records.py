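"""Data model and I/O for fire-history registers and trap-catch tables.

A fire register is a flat table of fire events — planar coordinates (metres),
total burned area (m²) and calendar year — of the kind kept by national civil
contingencies agencies. Each fire is stored with its centre coordinates only;
the register records total area but not perimeter, so a circular extent around
the centre is the only geometry available. A trap-catch table holds, per
sampling site, the number of caught individuals and species in each
classification group (pyrophilic / non-pyrophilic / obligate saproxylic).

Coordinates must already be in a projected planar CRS in metres (e.g. a
national grid); no reprojection is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: classification groups; labels are NOT mutually exclusive (a pyrophilic
#: species may also be saproxylic)
GROUPS = ("pyrophilic", "non_pyrophilic", "saproxylic")

FIRE_COLUMNS = ("fire_id", "x_m", "y_m", "area_m2", "year")
CATCH_COLUMNS = (
    "site_id", "x_m", "y_m", "sampling_year",
    "n_ind_total", "n_ind_pyro", "n_ind_nonpyro", "n_ind_sapro",
    "n_sp_total", "n_sp_pyro", "n_sp_nonpyro", "n_sp_sapro",
)

_GROUP_SUFFIX = {"pyrophilic": "pyro", "non_pyrophilic": "nonpyro", "saproxylic": "sapro"}


@dataclass(frozen=True)
class FireRecord:
    """One fire event: centre location, total burned area and year."""

    fire_id: str
    x_m: float
    y_m: float
    area_m2: float
    year: int

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise ValidationError(f"fire {self.fire_id!r}: area_m2 must be > 0, got {self.area_m2}")

    @property
    def radius_m(self) -> float:
        """Radius of the assumed circular extent, sqrt(area / pi)."""
        return math.sqrt(self.area_m2 / math.pi)


@dataclass(frozen=True)
class CatchCounts:
    """Per-site catch counts: totals and per-group counts, for individuals
    and for species. Group counts may overlap but each must stay within the
    corresponding total."""

    n_ind_total: int
    n_ind_pyro: int
    n_ind_nonpyro: int
    n_ind_sapro: int
    n_sp_total: int
    n_sp_pyro: int
    n_sp_nonpyro: int
    n_sp_sapro: int

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValidationError(f"count column {name!r} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"count column {name!r} must be >= 0, got {v}")
        for level, total in (("ind", self.n_ind_total), ("sp", self.n_sp_total)):
            for suffix in _GROUP_SUFFIX.values():
                col = f"n_{level}_{suffix}"
                if getattr(self, col) > total:
                    raise ValidationError(
                        f"count column {col!r} ({getattr(self, col)}) exceeds total "
                        f"n_{level}_total ({total})"
                    )

    def individuals(self, group: str) -> int:
        return getattr(self, f"n_ind_{_group_suffix(group)}")

    def species(self, group: str) -> int:
        return getattr(self, f"n_sp_{_group_suffix(group)}")

    def count(self, group: str, level: str) -> tuple[int, int]:
        """Return (group count, total) for the requested level."""
        if level == "individuals":
            return self.individuals(group), self.n_ind_total
        if level == "species":
            return self.species(group), self.n_sp_total
        raise ValidationError(f"unknown level {level!r}; valid levels: individuals, species")


def _group_suffix(group: str) -> str:
    try:
        return _GROUP_SUFFIX[group]
    except KeyError:
        raise ValidationError(
            f"unknown group {group!r}; valid groups: {', '.join(GROUPS)}"
        ) from None


@dataclass(frozen=True)
class TrapSite:
    """One sampling site: location, sampling year and (optionally) catches."""

    site_id: str
    x_m: float
    y_m: float
    sampling_year: int
    counts: CatchCounts | None = None


@dataclass
class FireSet:
    """An ordered collection of fire records."""

    records: list[FireRecord] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FireRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FireSet) and self.records == other.records

    # -- array views used by the vectorized kernel --------------------------
    def xy(self) -> np.ndarray:
        """(n, 2) array of centre coordinates in metres."""
        return np.array([[f.x_m, f.y_m] for f in self.records], dtype=float).reshape(-1, 2)

    def areas_m2(self) -> np.ndarray:
        return np.array([f.area_m2 for f in self.records], dtype=float)

    def years(self) -> np.ndarray:
        return np.array([f.year for f in self.records], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fire_id": [f.fire_id for f in self.records],
                "x_m": [f.x_m for f in self.records],
                "y_m": [f.y_m for f in self.records],
                "area_m2": [f.area_m2 for f in self.records],
                "year": [f.year for f in self.records],
            }
        )


def time_since_fire(sampling_year: int, fire_year: int) -> int:
    """Whole years elapsed between a fire and sampling (T = sampling − fire).

    Fires must be strictly prior to sampling, so T >= 1; the register carries
    no within-year timing, hence integer calendar-year differences.
    """
    t = int(sampling_year) - int(fire_year)
    if t < 1:
        raise ValidationError(
            f"fire year {fire_year} is not prior to sampling year {sampling_year}"
        )
    return t


def burned_forest_percent(total_burned_km2: float, forested_km2: float) -> float:
    """Percentage of the forested area burned over the register window."""
    if forested_km2 <= 0:
        raise ValidationError("forested_km2 must be positive")
    return 100.0 * total_burned_km2 / forested_km2


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, comment="#")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _numeric(df: pd.DataFrame, col: str, path: Path, integer: bool = False) -> pd.Series:
    """Convert a column, reporting the 1-based data row of the first bad cell.

    Cells are parsed with ``float()`` (correctly rounded, unlike pandas'
    fast string parser) so written datasets reload bit-identically.
    """
    raw = df[col]
    out = np.full(len(raw), np.nan)
    for i, cell in enumerate(raw):
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            continue
        text = str(cell).strip()
        if text == "":
            continue
        try:
            value = float(text)
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric value {cell!r} in column {col!r}, data row {i + 1}"
            ) from None
        if integer and value % 1 != 0:
            raise ParseError(f"{path}: non-integer value in column {col!r}, data row {i + 1}")
        out[i] = value
    return pd.Series(out, index=raw.index)


def load_fires(
    path: str | Path,
    min_area_m2: float = 100.0,
    year_range: tuple[int, int] = (1999, 2010),
) -> FireSet:
    """Load a fire register, applying the register's filtering rules.

    Records with burned area below ``min_area_m2`` (inclusive threshold:
    registers round, so exactly-at-cutoff records are common and kept) or
    with a year outside ``year_range`` are dropped. Rows with missing
    coordinates are dropped with a logged count — the original register
    resolved such fires manually with local fire authorities, which a
    pipeline cannot do.
    """
    path = Path(path)
    df = _read_table(path, FIRE_COLUMNS)
    if df.empty:
        logger.warning("%s: no data rows; returning empty FireSet", path)
        return FireSet([])

    x = _numeric(df, "x_m", path)
    y = _numeric(df, "y_m", path)
    area = _numeric(df, "area_m2", path)
    year = _numeric(df, "year", path, integer=True)

    missing_xy = x.isna() | y.isna()
    if missing_xy.any():
        logger.info("%s: dropped %d rows with missing coordinates", path, int(missing_xy.sum()))

    lo, hi = year_range
    keep = ~missing_xy & (area >= min_area_m2) & (year >= lo) & (year <= hi)
    n_area = int((~missing_xy & (area < min_area_m2)).sum())
    n_year = int((~missing_xy & (area >= min_area_m2) & ~((year >= lo) & (year <= hi))).sum())
    if n_area or n_year:
        logger.info(
            "%s: dropped %d rows below %.0f m2 and %d rows outside years [%d, %d]",
            path, n_area, min_area_m2, n_year, lo, hi,
        )

    records = [
        FireRecord(
            fire_id=str(df["fire_id"].iloc[i]),
            x_m=float(x.iloc[i]),
            y_m=float(y.iloc[i]),
            area_m2=float(area.iloc[i]),
            year=int(year.iloc[i]),
        )
        for i in np.flatnonzero(keep.to_numpy())
    ]
    if not records:
        logger.warning("%s: no fires survive filtering; returning empty FireSet", path)
    return FireSet(records)


def write_fires(fires: FireSet, path: str | Path) -> None:
    # %.17g keeps float round-trips exact across write/reload
    fires.to_frame().to_csv(path, index=False, float_format="%.17g")


def load_catches(path: str | Path) -> list[TrapSite]:
    """Load a per-site trap-catch table, enforcing the count invariants."""
    path = Path(path)
    df = _read_table(path, CATCH_COLUMNS)
    if df.empty:
        return []

    x = _numeric(df, "x_m", path)
    y = _numeric(df, "y_m", path)
    syear = _numeric(df, "sampling_year", path, integer=True)
    counts = {c: _numeric(df, c, path, integer=True) for c in CATCH_COLUMNS[4:]}

    sites: list[TrapSite] = []
    seen: set[str] = set()
    for i in range(len(df)):
        sid = str(df["site_id"].iloc[i])
        if sid in seen:
            raise ValidationError(f"{path}: duplicate site_id {sid!r}")
        seen.add(sid)
        try:
            cc = CatchCounts(**{c: int(counts[c].iloc[i]) for c in counts})
        except ValidationError as exc:
            raise ValidationError(f"{path}: site {sid!r}: {exc}") from None
        sites.append(
            TrapSite(
                site_id=sid,
                x_m=float(x.iloc[i]),
                y_m=float(y.iloc[i]),
                sampling_year=int(syear.iloc[i]),
                counts=cc,
            )
        )
    return sites


def write_catches(sites: Iterable[TrapSite], path: str | Path) -> None:
    rows = []
    for s in sites:
        if s.counts is None:
            raise ValidationError(f"site {s.site_id!r} has no catch counts to write")
        row = {"site_id": s.site_id, "x_m": s.x_m, "y_m": s.y_m, "sampling_year": s.sampling_year}
        row.update({c: getattr(s.counts, c) for c in CATCH_COLUMNS[4:]})
        rows.append(row)
    pd.DataFrame(rows, columns=list(CATCH_COLUMNS)).to_csv(path, index=False, float_format="%.17g")
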
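"""Readers and writers for the text formats used in quantitative wood anatomy
(QWA) dendroclimatology.

Four families of files are handled, all plain text:

* **Per-cell anatomical tables** — long-form delimited exports in the style of
  ROXAS/RAPTOR output, one row per tracheid with lumen diameter (LD, µm) and
  cell wall thickness (CWT, µm), keyed by tree / core / ring year / radial
  file / cell rank.
* **Tucson ``.rwl`` ring-width files** — the standard fixed-width decadal
  exchange format. Both common dialects are accepted on read (terminator
  ``999`` with widths in 0.01 mm, and ``-9999`` with widths in 0.001 mm);
  writes always emit the 0.01 mm dialect.
* **Monthly climate tables** — a year column followed by twelve monthly
  values, with an explicit missing-value code (never zero).
* **Sector chronology tables** and **gridded monthly climate** in long
  delimited layout (year, month, lat, lon, value).

All readers validate strictly and raise :class:`FormatError` or
:class:`ValidationError` with row/line context instead of silently coercing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "FormatError",
    "ValidationError",
    "CellDialect",
    "CELL_COLUMNS",
    "RingWidthSet",
    "ClimateTable",
    "GridField",
    "read_cell_table",
    "write_cell_table",
    "validate_cell_table",
    "read_rwl",
    "write_rwl",
    "read_monthly_climate",
    "write_monthly_climate",
    "read_chronology",
    "write_chronology",
    "read_grid_table",
    "write_grid_table",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """A file parsed cleanly but violates a domain invariant."""


# ---------------------------------------------------------------------------
# per-cell anatomical tables
# ---------------------------------------------------------------------------

#: canonical column order of an in-memory cell table
CELL_COLUMNS = ("tree", "core", "year", "file", "rank", "ld", "cwt")

#: columns forming the unique key of a cell record
CELL_KEY = ("tree", "core", "year", "file", "rank")


@dataclass(frozen=True)
class CellDialect:
    """Delimiter and column-name mapping for a cell-table export.

    ROXAS export headers vary by version, so the mapping from canonical
    column names (``tree``, ``core``, ``year``, ``file``, ``rank``, ``ld``,
    ``cwt``) to the names actually present in the file is configurable.
    """

    sep: str = ","
    columns: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in CELL_COLUMNS}
    )


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a cell table.

    Checks required columns, positivity of ``ld``/``cwt``, cell ranks ≥ 1 and
    key uniqueness; returns a copy sorted by (tree, core, year, file, rank).
    """
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table is missing required column(s): {missing}")
    df = df.loc[:, list(CELL_COLUMNS)].copy()
    df["year"] = df["year"].astype(int)
    df["rank"] = df["rank"].astype(int)
    for col in ("ld", "cwt"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~(vals > 0)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise ValidationError(
                f"non-positive or non-numeric {col} at row(s) {rows}"
            )
        df[col] = vals.astype(float)
    if (df["rank"] < 1).any():
        rows = df.index[df["rank"] < 1].tolist()[:5]
        raise ValidationError(f"cell rank < 1 at row(s) {rows}")
    dup = df.duplicated(subset=list(CELL_KEY), keep=False)
    if dup.any():
        keys = (
            df.loc[dup, list(CELL_KEY)]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ValidationError(
            "duplicated cell key(s) (tree, core, year, file, rank): "
            + "; ".join(str(k) for k in list(keys)[:5])
        )
    return df.sort_values(list(CELL_KEY), kind="mergesort").reset_index(drop=True)


def read_cell_table(path, dialect: CellDialect | None = None) -> pd.DataFrame:
    """Read a per-cell anatomical measurement table.

    Parameters
    ----------
    path
        Delimited text file, one row per cell.
    dialect
        Delimiter and column-name mapping; defaults to comma-separated
        canonical names.
    """
    dialect = dialect or CellDialect()
    raw = pd.read_csv(path, sep=dialect.sep)
    missing = [v for v in dialect.columns.values() if v not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(raw.columns)}"
        )
    inverse = {v: k for k, v in dialect.columns.items()}
    df = raw.rename(columns=inverse)
    return validate_cell_table(df)


def write_cell_table(df: pd.DataFrame, path, dialect: CellDialect | None = None) -> None:
    """Write a validated cell table; inverse of :func:`read_cell_table`."""
    dialect = dialect or CellDialect()
    out = validate_cell_table(df).rename(columns=dict(dialect.columns))
    out.to_csv(path, sep=dialect.sep, index=False)


# ---------------------------------------------------------------------------
# Tucson .rwl ring widths
# ---------------------------------------------------------------------------


@dataclass
class RingWidthSet:
    """Ring-width series in mm keyed by core label.

    ``series`` maps core id → ``(first_year, widths)`` with widths a 1-D
    float array (mm) covering contiguous years.
    """

    series: dict[str, tuple[int, np.ndarray]]

    def years(self, core: str) -> np.ndarray:
        first, w = self.series[core]
        return np.arange(first, first + len(w))

    def to_frame(self) -> pd.DataFrame:
        """Year × core DataFrame with NaN outside each core's span."""
        cols = {}
        for cid, (first, w) in self.series.items():
            cols[cid] = pd.Series(w, index=np.arange(first, first + len(w)))
        return pd.DataFrame(cols)


def read_rwl(path) -> RingWidthSet:
    """Read a Tucson-format ring-width file.

    Series ids occupy the first 8 characters; each line carries the first
    year of the values on that line followed by up to ten widths. The
    terminator selects the unit dialect: ``999`` → 0.01 mm, ``-9999`` →
    0.001 mm.
    """
    series: dict[str, tuple[int, np.ndarray]] = {}
    current: str | None = None
    first_year = 0
    widths: list[int] = []
    expected_year: int | None = None

    def _close(unit: float, lineno: int) -> None:
        nonlocal current, widths
        if current is None:
            raise FormatError(f"line {lineno}: terminator before any data")
        if current in series:
            raise FormatError(f"line {lineno}: duplicate series id {current!r}")
        series[current] = (first_year, np.asarray(widths, dtype=float) * unit)
        current = None
        widths = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            tokens = line[8:].split()
            if len(tokens) < 2:
                raise FormatError(f"line {lineno}: expected a year and values")
            try:
                year = int(tokens[0])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad year field {tokens[0]!r}") from exc
            if current is None:
                current, first_year = sid, year
                expected_year = year
            elif sid != current:
                raise FormatError(
                    f"line {lineno}: series {current!r} not terminated before {sid!r}"
                )
            elif year != expected_year:
                raise FormatError(
                    f"line {lineno}: non-contiguous decade start {year} "
                    f"(expected {expected_year})"
                )
            terminated = False
            for tok in tokens[1:]:
                try:
                    val = int(tok)
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: bad width value {tok!r}") from exc
                if val == 999:
                    _close(0.01, lineno)
                    terminated = True
                    break
                if val == -9999:
                    _close(0.001, lineno)
                    terminated = True
                    break
                if val < 0:
                    raise FormatError(
                        f"line {lineno}: negative width {val} is not a known terminator"
                    )
                widths.append(val)
            if not terminated:
                expected_year = year + len(tokens) - 1
    if current is not None:
        raise FormatError(f"series {current!r} has no terminator")
    if not series:
        raise FormatError(f"{path}: no ring-width series found")
    return RingWidthSet(series=series)


def write_rwl(rws: RingWidthSet, path) -> None:
    """Write a :class:`RingWidthSet` in the 0.01 mm / ``999`` Tucson dialect."""
    lines = []
    for cid, (first, w) in rws.series.items():
        if len(cid) > 8:
            raise ValidationError(f"series id {cid!r} exceeds 8 characters")
        vals = [int(round(x * 100)) for x in w]
        year = first
        i = 0
        while i < len(vals):
            decade_end = (year // 10) * 10 + 9
            take = min(decade_end - year + 1, len(vals) - i)
            chunk = vals[i : i + take]
            i += take
            row = f"{cid:<8}{year:4d}" + "".join(f"{v:6d}" for v in chunk)
            if i == len(vals):
                if len(chunk) < 10:
                    row += f"{999:6d}"
                else:
                    row += "\n" + f"{cid:<8}{year + take:4d}" + f"{999:6d}"
            lines.append(row)
            year += take
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# monthly climate
# ---------------------------------------------------------------------------

CLIMATE_VARIABLES = ("tmax", "tmean", "tmin", "precip", "spei")


@dataclass
class ClimateTable:
    """Monthly site climate: a contiguous year axis × 12 monthly values.

    Missing values are NaN — never zero. ``variable`` is one of
    ``tmax``/``tmean``/``tmin`` (°C), ``precip`` (mm) or ``spei``
    (dimensionless).
    """

    variable: str
    years: np.ndarray
    values: np.ndarray  # (n_years, 12), NaN = missing

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.years), 12):
            raise ValidationError(
                f"climate values shape {self.values.shape} does not match "
                f"{len(self.years)} years × 12 months"
            )
        if len(self.years) and np.any(np.diff(self.years) != 1):
            raise ValidationError("climate year axis must be contiguous")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.years, columns=np.arange(1, 13)
        )


def read_monthly_climate(
    path, variable: str, sep: str = ",", missing: float = -9999.0
) -> ClimateTable:
    """Read a year × 12 monthly climate table.

    Gap years are inserted as all-missing rows so the year axis is always
    contiguous; values equal to ``missing`` become NaN.
    """
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] != 13:
        raise FormatError(
            f"{path}: expected a year column plus 12 monthly columns, "
            f"got {df.shape[1]} columns"
        )
    years = df.iloc[:, 0].astype(int).to_numpy()
    if len(np.unique(years)) != len(years):
        dups = pd.Series(years)[pd.Series(years).duplicated()].unique()
        raise FormatError(f"{path}: duplicate year(s) {dups.tolist()}")
    order = np.argsort(years)
    years = years[order]
    vals = df.iloc[:, 1:].to_numpy(dtype=float)[order]
    vals[vals == missing] = np.nan
    full = np.arange(years[0], years[-1] + 1)
    out = np.full((len(full), 12), np.nan)
    out[np.searchsorted(full, years)] = vals
    return ClimateTable(variable=variable, years=full, values=out)


def write_monthly_climate(
    ct: ClimateTable, path, sep: str = ",", missing: float = -9999.0
) -> None:
    """Write a :class:`ClimateTable`; inverse of :func:`read_monthly_climate`."""
    vals = ct.values.copy()
    vals[np.isnan(vals)] = missing
    df = pd.DataFrame(vals, columns=[f"m{m:02d}" for m in range(1, 13)])
    df.insert(0, "year", ct.years)
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# chronology tables
# ---------------------------------------------------------------------------


def write_chronology(chron, path, sep: str = ",") -> None:
    """Write sector chronologies as year, per-sector index, sample depth.

    ``chron`` is a single ``SectorChronology`` or a mapping of sector label →
    ``SectorChronology`` (see :mod:`qwa.chronology`). Values survive a
    round-trip to 6 significant digits. Header lines starting with ``#``
    carry the method tag.
    """
    from .chronology import SectorChronology  # local import avoids a cycle

    if isinstance(chron, SectorChronology):
        chron = {chron.sector: chron}
    if not chron:
        raise ValidationError("empty chronology")
    labels = list(chron.keys())
    years = None
    for c in chron.values():
        if len(c.years) == 0:
            raise ValidationError(f"chronology sector {c.sector!r} is empty")
        years = c.years if years is None else years
        if not np.array_equal(c.years, years):
            raise ValidationError("sector chronologies cover different year spans")
    method = next(iter(chron.values())).method
    df = pd.DataFrame(
        {lab: chron[lab].index for lab in labels}, index=years
    )
    df["depth"] = next(iter(chron.values())).depth
    with open(path, "w") as fh:
        fh.write(f"# qwa chronology method={method}\n")
        fh.write("year" + sep + sep.join(df.columns) + "\n")
        for year, row in df.iterrows():
            fields = [f"{v:.6g}" if np.isfinite(v) else "NA" for v in row]
            fh.write(str(year) + sep + sep.join(fields) + "\n")


def read_chronology(path, sep: str = ","):
    """Read a chronology table written by :func:`write_chronology`.

    Returns ``(mapping sector → SectorChronology, method)``.
    """
    from .chronology import SectorChronology

    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_start = 0
    for line in lines:
        if line.startswith("#"):
            data_start += 1
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        else:
            break
    header = lines[data_start].strip().split(sep)
    if header[0] != "year" or header[-1] != "depth":
        raise FormatError(f"{path}: unexpected chronology header {header}")
    body = [ln.strip().split(sep) for ln in lines[data_start + 1 :] if ln.strip()]
    if not body:
        raise FormatError(f"{path}: chronology has no data rows")
    years = np.array([int(r[0]) for r in body])
    vals = np.array(
        [[np.nan if v == "NA" else float(v) for v in r[1:]] for r in body]
    )
    method = meta.get("method", "arithmetic")
    depth = vals[:, -1]
    out = {}
    for j, lab in enumerate(header[1:-1]):
        out[lab] = SectorChronology(
            sector=lab, years=years, index=vals[:, j], depth=depth, method=method
        )
    return out, method


# ---------------------------------------------------------------------------
# gridded climate
# ---------------------------------------------------------------------------


@dataclass
class GridField:
    """Gridded monthly climate: values shaped (year, month, lat, lon)."""

    variable: str
    years: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for name, coord in (("lats", self.lats), ("lons", self.lons)):
            if len(coord) > 1 and not (
                np.all(np.diff(coord) > 0) or np.all(np.diff(coord) < 0)
            ):
                raise ValidationError(f"{name} must be strictly monotone")
        expect = (len(self.years), 12, len(self.lats), len(self.lons))
        if self.values.shape != expect:
            raise ValidationError(
                f"grid values shape {self.values.shape} != {expect}"
            )

    def to_xarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            dims=("year", "month", "lat", "lon"),
            coords={
                "year": self.years,
                "month": np.arange(1, 13),
                "lat": self.lats,
                "lon": self.lons,
            },
            name=self.variable,
        )


def write_grid_table(grid: GridField, path, sep: str = ",") -> None:
    """Write a grid field as a long table (year, month, lat, lon, value)."""
    da = grid.to_xarray()
    df = da.to_dataframe().reset_index()
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


def read_grid_table(path, variable: str | None = None, sep: str = ",") -> GridField:
    """Read a long-format grid table written by :func:`write_grid_table`."""
    df = pd.read_csv(path, sep=sep)
    value_col = df.columns[-1]
    for col in ("year", "month", "lat", "lon"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing grid column {col!r}")
    da = df.set_index(["year", "month", "lat", "lon"])[value_col].to_xarray()
    return GridField(
        variable=variable or value_col,
        years=da["year"].values,
        lats=da["lat"].values,
        lons=da["lon"].values,
        values=da.values,
    )
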
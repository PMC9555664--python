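"""Egg morphometrics: from calliper measurements to annual mean-volume series.

Egg volume is computed from length ``L`` and width ``W`` (both in mm) as

    V = beta * L * W**2

with a species-specific dimensionless constant ``beta`` chosen so that the
result is in cm^3.  Volumes are aggregated clutch-first: eggs are averaged
within each nest-by-year clutch, and the clutch means are then averaged
within each year.  This matters for the gull, which lays multi-egg clutches,
because it weights every clutch equally regardless of clutch size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, MissingYearError, SchemaError

#: Species-specific volume constants (mm inputs -> cm^3 output).
SPECIES_BETA: dict[str, float] = {
    "shearwater": 0.509e-3,
    "gull": 0.476e-3,
}

EGGS_CSV_COLUMNS = ["species", "year", "nest_id", "length_mm", "width_mm"]
SERIES_CSV_COLUMNS = ["species", "year", "mean_volume_cm3", "n_clutches", "sd_volume_cm3"]

DEFAULT_STUDY_WINDOW = (2002, 2019)


@dataclass(frozen=True)
class EggRecord:
    """One measured egg."""

    species: str
    year: int
    nest_id: str
    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise InvalidMeasurementError(
                f"non-positive egg measurement: L={self.length_mm}, W={self.width_mm}"
            )
        if self.width_mm > self.length_mm:
            warnings.warn(
                f"egg width {self.width_mm} mm exceeds length {self.length_mm} mm "
                f"(nest {self.nest_id}, {self.year}): possible transcription swap",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AnnualSeries:
    """Per-species annual mean-volume time series over contiguous years."""

    species: str
    years: np.ndarray
    mean_volume_cm3: np.ndarray
    n_clutches: np.ndarray
    sd_volume_cm3: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        if len(years) and not np.array_equal(np.diff(years), np.ones(len(years) - 1, dtype=int)):
            raise MissingYearError(
                f"{self.species}: years are not contiguous: {years.tolist()}"
            )
        if np.any(np.asarray(self.n_clutches) < 1):
            raise MissingYearError(f"{self.species}: a retained year has zero clutches")

    def __len__(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "year": np.asarray(self.years, dtype=int),
                "mean_volume_cm3": self.mean_volume_cm3,
                "n_clutches": np.asarray(self.n_clutches, dtype=int),
                "sd_volume_cm3": self.sd_volume_cm3,
            }
        )


def egg_volume(length_mm, width_mm, beta) -> float:
    """Volume in cm^3 of an egg of length ``length_mm`` and width ``width_mm``.

    Vectorized over array inputs.  Raises :class:`InvalidMeasurementError`
    for non-positive lengths, widths or constants.
    """
    length_mm = np.asarray(length_mm, dtype=float)
    width_mm = np.asarray(width_mm, dtype=float)
    if np.any(length_mm <= 0) or np.any(width_mm <= 0):
        raise InvalidMeasurementError("length and width must be positive")
    if np.any(np.asarray(beta, dtype=float) <= 0):
        raise InvalidMeasurementError("volume constant beta must be positive")
    out = beta * length_mm * width_mm**2
    return float(out) if out.ndim == 0 else out


def annual_series(
    records: list[EggRecord] | pd.DataFrame,
    constants: dict[str, float] | None = None,
    study_window: tuple[int, int] = DEFAULT_STUDY_WINDOW,
    *,
    clutch_first: bool = True,
) -> dict[str, AnnualSeries]:
    """Aggregate egg records into one annual mean-volume series per species.

    Aggregation is clutch-first by default: egg volumes are averaged within
    each ``nest_id`` x ``year`` clutch, then clutch means are averaged within
    the year.  ``clutch_first=False`` pools all eggs of a year directly.

    A year inside ``study_window`` with no clutches for a species is an
    error, because the downstream synchrony analysis requires contiguous
    series.
    """
    constants = dict(SPECIES_BETA if constants is None else constants)
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        raise MissingYearError("no egg records supplied")

    lo, hi = study_window
    outside = df[(df["year"] < lo) | (df["year"] > hi)]
    if not outside.empty:
        raise SchemaError(
            f"{len(outside)} record(s) outside the study window {lo}-{hi} "
            f"(first offending year: {int(outside['year'].iloc[0])})"
        )

    unknown = set(df["species"]) - set(constants)
    if unknown:
        raise SchemaError(f"no volume constant for species: {sorted(unknown)}")

    df["volume_cm3"] = [
        egg_volume(l, w, constants[s])
        for s, l, w in zip(df["species"], df["length_mm"], df["width_mm"])
    ]

    out: dict[str, AnnualSeries] = {}
    for species, sdf in df.groupby("species", sort=True):
        if clutch_first:
            clutch_means = sdf.groupby(["year", "nest_id"])["volume_cm3"].mean()
            per_year = clutch_means.groupby(level="year")
        else:
            per_year = sdf.groupby("year")["volume_cm3"]
        stats = per_year.agg(["mean", "count", "std"]).sort_index()
        missing = sorted(set(range(lo, hi + 1)) - set(stats.index))
        if missing:
            raise MissingYearError(
                f"{species}: no clutches in year(s) {missing} inside window {lo}-{hi}"
            )
        out[str(species)] = AnnualSeries(
            species=str(species),
            years=stats.index.to_numpy(dtype=int),
            mean_volume_cm3=stats["mean"].to_numpy(),
            n_clutches=stats["count"].to_numpy(dtype=int),
            sd_volume_cm3=stats["std"].fillna(0.0).to_numpy(),
        )
    return out


def read_eggs_csv(path) -> pd.DataFrame:
    """Read an eggs CSV (``species,year,nest_id,length_mm,width_mm``)."""
    df = pd.read_csv(path, dtype={"nest_id": str})
    missing = [c for c in EGGS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    bad_species = set(df["species"].unique()) - set(SPECIES_BETA)
    if bad_species:
        row = int(df.index[df["species"].isin(bad_species)][0]) + 2  # 1-based + header
        raise SchemaError(
            f"{path}: unknown species label(s) {sorted(bad_species)} (first at row {row})"
        )
    for col in ("year", "length_mm", "width_mm"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = int(parsed.index[parsed.isna()][0]) + 2
            raise SchemaError(f"{path}: unparsable value in column '{col}' at row {row}")
        df[col] = parsed
    df["year"] = df["year"].astype(int)
    return df[EGGS_CSV_COLUMNS]


def write_eggs_csv(df: pd.DataFrame, path) -> None:
    df[EGGS_CSV_COLUMNS].to_csv(path, index=False)


def write_series_csv(series: dict[str, AnnualSeries], path) -> None:
    """Write per-species annual series to one long-format CSV."""
    pd.concat([s.to_frame() for s in series.values()], ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_series_csv(path) -> dict[str, AnnualSeries]:
    df = pd.read_csv(path)
    missing = [c for c in SERIES_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out = {}
    for species, sdf in df.groupby("species", sort=True):
        sdf = sdf.sort_values("year")
        out[str(species)] = AnnualSeries(
            species=str(species),
            years=sdf["year"].to_numpy(dtype=int),
            mean_volume_cm3=sdf["mean_volume_cm3"].to_numpy(),
            n_clutches=sdf["n_clutches"].to_numpy(dtype=int),
            sd_volume_cm3=sdf["sd_volume_cm3"].to_numpy(),
        )
    return out
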
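"""Input readers: site tables, monthly climate (tables or raster stacks),
and annual atmospheric CO2 resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geotiff import read_geotiff, sample_buffer, sample_point

logger = logging.getLogger(__name__)

#: calendar days per month, non-leap, January first
MONTH_DAYS: tuple[int, ...] = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


class ConfigurationError(ValueError):
    """Malformed input layout: missing columns, wrong file counts, ..."""


class ValidationError(ValueError):
    """Well-formed input carrying invalid values."""


class Co2LookupError(KeyError):
    """Requested year absent from the CO2 table and no fallback given."""


@dataclass(frozen=True)
class SiteRecord:
    """One forest plot: location, observation year, observed productivity."""

    site_id: str
    lon: float
    lat: float
    year: int | None = None
    tnpp_obs: float | None = None
    climate_zone: str | None = None
    phenology: str | None = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"{self.site_id}: lon {self.lon} out of range")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"{self.site_id}: lat {self.lat} out of range")
        if self.tnpp_obs is not None and self.tnpp_obs <= 0:
            raise ValidationError(
                f"{self.site_id}: tnpp_obs must be positive, got {self.tnpp_obs}"
            )


@dataclass
class MonthlyClimate:
    """12 monthly mean temperatures (degC) and mean daily solar radiation
    (kJ m-2 day-1), January first.  Missing months are NaN."""

    temp: np.ndarray
    srad: np.ndarray
    month_days: tuple[int, ...] = MONTH_DAYS

    def __post_init__(self) -> None:
        self.temp = np.asarray(self.temp, dtype=float)
        self.srad = np.asarray(self.srad, dtype=float)
        if self.temp.shape != (12,) or self.srad.shape != (12,):
            raise ValidationError("temp and srad must each have 12 entries")
        if len(self.month_days) != 12 or sum(self.month_days) != 365:
            raise ValidationError("month_days must be 12 entries summing to 365")
        if np.any(self.srad[np.isfinite(self.srad)] < 0):
            raise ValidationError("negative solar radiation")

    @property
    def missing_months(self) -> list[int]:
        """0-based indices of months missing either variable."""
        bad = ~np.isfinite(self.temp) | ~np.isfinite(self.srad)
        return [int(i) for i in np.nonzero(bad)[0]]

    def is_complete(self) -> bool:
        return not self.missing_months


@dataclass(frozen=True)
class Co2Table:
    """Annual mean atmospheric CO2 (ppm) keyed by calendar year."""

    ppm_by_year: Mapping[int, float]

    def __post_init__(self) -> None:
        years = list(self.ppm_by_year)
        if years != sorted(set(years)):
            raise ValidationError("CO2 table years must be strictly increasing")
        for year, ppm in self.ppm_by_year.items():
            if not 150.0 < ppm < 1000.0:
                raise ValidationError(f"CO2 value {ppm} ppm for {year} implausible")

    def __contains__(self, year: int) -> bool:
        return year in self.ppm_by_year


_TEMP_COLS = [f"temp_{m:02d}" for m in range(1, 13)]
_SRAD_COLS = [f"srad_{m:02d}" for m in range(1, 13)]


def read_sites(path: str | Path, delimiter: str = ",") -> list[SiteRecord]:
    """Read a site table; rows with invalid coordinates are dropped with a
    logged warning, structural problems raise."""
    df = pd.read_csv(path, sep=delimiter, dtype={"site_id": str})
    for col in ("site_id", "lon", "lat"):
        if col not in df.columns:
            raise ConfigurationError(f"site table missing required column '{col}'")
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValidationError(f"duplicate site_id values: {dupes}")
    sites: list[SiteRecord] = []
    for idx, row in df.iterrows():
        try:
            year = row.get("year")
            tnpp = row.get("tnpp_obs")
            sites.append(
                SiteRecord(
                    site_id=str(row["site_id"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    year=None if pd.isna(year) else int(year),
                    tnpp_obs=None if pd.isna(tnpp) else float(tnpp),
                    climate_zone=_opt_str(row.get("climate_zone")),
                    phenology=_opt_str(row.get("phenology")),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            logger.warning("row %d rejected: %s", idx, exc)
    return sites


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if pd.isna(value):
        return None
    return str(value)


def read_climate_table(path: str | Path, delimiter: str = ",") -> dict[str, MonthlyClimate]:
    """Read per-site monthly climate from a 1+24 column delimited table."""
    df = pd.read_csv(path, sep=delimiter, dtype={"site_id": str})
    missing = [c for c in ["site_id", *_TEMP_COLS, *_SRAD_COLS] if c not in df.columns]
    if missing:
        raise ConfigurationError(f"climate table missing columns: {missing}")
    out: dict[str, MonthlyClimate] = {}
    for _, row in df.iterrows():
        temp = row[_TEMP_COLS].to_numpy(dtype=float)
        srad = row[_SRAD_COLS].to_numpy(dtype=float)
        out[str(row["site_id"])] = MonthlyClimate(temp=temp, srad=srad)
    return out


def extract_monthly(
    sites: Sequence[SiteRecord],
    temp_rasters: Sequence[str | Path],
    srad_rasters: Sequence[str | Path],
    buffer_m: float | None = None,
) -> dict[str, MonthlyClimate]:
    """Sample 12+12 monthly rasters at each site.

    Without a buffer the value of the cell containing the point is used;
    with a buffer, the unweighted mean over valid cells whose centers fall
    within ``buffer_m`` meters of the site.  NoData or out-of-extent
    samples become missing months (NaN).
    """
    if len(temp_rasters) != 12 or len(srad_rasters) != 12:
        raise ConfigurationError(
            f"expected 12 rasters per variable, got {len(temp_rasters)} temp "
            f"and {len(srad_rasters)} srad"
        )
    temp_grids = [read_geotiff(p) for p in temp_rasters]
    srad_grids = [read_geotiff(p) for p in srad_rasters]
    out: dict[str, MonthlyClimate] = {}
    for site in sites:
        temp = np.full(12, np.nan)
        srad = np.full(12, np.nan)
        for m in range(12):
            for grids, dest in ((temp_grids, temp), (srad_grids, srad)):
                if buffer_m is None:
                    val = sample_point(grids[m], site.lon, site.lat)
                else:
                    val = sample_buffer(grids[m], site.lon, site.lat, buffer_m)
                if val is not None:
                    dest[m] = val
        if np.all(~np.isfinite(temp)) and np.all(~np.isfinite(srad)):
            logger.warning("site %s: no raster coverage, all months missing", site.site_id)
        out[site.site_id] = MonthlyClimate(temp=temp, srad=srad)
    return out


def read_co2_table(path: str | Path, delimiter: str = ",") -> Co2Table:
    """Read a two-column (year, ppm) delimited table."""
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] < 2:
        raise ConfigurationError("CO2 table needs two columns: year, ppm")
    year_col, ppm_col = df.columns[:2]
    pairs = {int(y): float(p) for y, p in zip(df[year_col], df[ppm_col])}
    return Co2Table(ppm_by_year=dict(sorted(pairs.items())))


def load_packaged_co2() -> Co2Table:
    """Annual Mauna Loa means shipped with the package (1959-2022)."""
    ref = resources.files("efit.data") / "co2_annual_maunaloa.csv"
    with resources.as_file(ref) as path:
        return read_co2_table(path)


def co2_for_year(
    year: int, table: Co2Table, fallback_ppm: float | None = None
) -> float:
    """Exact-year annual mean CO2; ``fallback_ppm`` if absent; never
    interpolated."""
    if year in table.ppm_by_year:
        return table.ppm_by_year[year]
    if fallback_ppm is not None:
        return float(fallback_ppm)
    raise Co2LookupError(f"no CO2 value for year {year} and no fallback provided")
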
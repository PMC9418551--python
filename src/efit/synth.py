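"""Synthetic climates, rasters, CO2 tables, and multi-zone site datasets
with closed-form expected answers, so every pipeline stage is testable
without external downloads.

The per-site truth table is computed by a deliberately independent,
straight-line transcription of the model formulas (no calls into
:mod:`efit.season` or :mod:`efit.lue_core`), making round-trip tests a
genuine dual-route check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate_io import MONTH_DAYS, MonthlyClimate, SiteRecord
from .geotiff import GridGeoref, write_geotiff

DEFAULT_ZONES_KEY = {"boreal": 0, "temperate": 1, "tropical": 2}


@dataclass(frozen=True)
class ZoneTemplate:
    """Sinusoidal annual climate with a July peak plus an observed-NPP
    distribution expressed as a fraction of the zone's analytic maximum."""

    name: str
    temp_mean: float
    temp_amplitude: float
    srad_mean: float
    srad_amplitude: float
    efit_fraction: float = 0.4
    phenology: str = "evergreen"

    def monthly_temp(self) -> np.ndarray:
        m = np.arange(1, 13)
        return self.temp_mean + self.temp_amplitude * np.cos(2 * np.pi * (m - 7) / 12)

    def monthly_srad(self) -> np.ndarray:
        m = np.arange(1, 13)
        srad = self.srad_mean + self.srad_amplitude * np.cos(2 * np.pi * (m - 7) / 12)
        return np.maximum(srad, 0.0)


#: three stylized zones spanning boreal to tropical conditions
DEFAULT_ZONES: tuple[ZoneTemplate, ...] = (
    ZoneTemplate("boreal", -2.0, 15.0, 9000.0, 7000.0, 0.25, "deciduous"),
    ZoneTemplate("temperate", 10.0, 10.0, 13000.0, 5000.0, 0.40, "deciduous"),
    ZoneTemplate("tropical", 26.0, 1.0, 17000.0, 1000.0, 0.55, "evergreen"),
)


@dataclass(frozen=True)
class SynthSpec:
    n_sites: int = 30
    zones: tuple[ZoneTemplate, ...] = DEFAULT_ZONES
    noise_sd: float = 0.0
    climate_jitter_sd: float = 0.0
    year: int = 2000
    co2_ppm: float = 369.71
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for z in self.zones:
            if not 0.0 < z.efit_fraction <= 1.5:
                raise ValueError(f"zone {z.name}: efit_fraction must be in (0, 1.5]")


def make_climate(
    zone: ZoneTemplate, seed: int | None = None, jitter_sd: float = 0.0
) -> MonthlyClimate:
    """Monthly climate from the zone's cosine series, optionally jittered."""
    temp = zone.monthly_temp()
    srad = zone.monthly_srad()
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        temp = temp + rng.normal(0.0, jitter_sd, 12)
        srad = np.maximum(srad + rng.normal(0.0, jitter_sd * 100.0, 12), 0.0)
    return MonthlyClimate(temp=temp.copy(), srad=srad.copy())


def analytic_truth(
    temp: np.ndarray, srad: np.ndarray, c_a: float
) -> dict[str, float]:
    """Straight-line transcription of the model for one site's 12 monthly
    values: growing season, compensation point, uptake chain, and maximum
    NPP.  Kept independent of the package's season/lue modules on purpose.
    """
    warm = [m for m in range(12) if np.isfinite(temp[m]) and temp[m] >= 0.0]
    g_days = sum(MONTH_DAYS[m] for m in warm)
    if not warm:
        return {
            "g_days": 0,
            "g_temp": math.nan,
            "g_srad": math.nan,
            "tnpp_tmax": 0.0,
        }
    g_temp = float(np.mean([temp[m] for m in warm]))
    g_srad = float(np.mean([srad[m] for m in warm]))
    gamma = math.exp(19.02 - 37.83 / (0.008314 * (g_temp + 273.15)))
    ci = c_a * 0.7
    wi = ci / (4.5 * ci + 10.5 * gamma)
    a = (1 - gamma / ci) * wi
    ec = a * 0.45 * 0.9
    tmax = g_srad * g_days * 0.45 * 0.9 * ec / 1000.0 / 18.2 * 10.0
    if a <= 0:
        tmax = 0.0
    return {"g_days": g_days, "g_temp": g_temp, "g_srad": g_srad, "tnpp_tmax": tmax}


def _site_grid(n_sites: int) -> GridGeoref:
    ncols = min(n_sites, 180)
    nrows = (n_sites + ncols - 1) // ncols
    return GridGeoref(
        west=-90.0, north=float(nrows), xres=1.0, yres=1.0, ncols=ncols, nrows=nrows
    )


def _site_lonlat(i: int, grid: GridGeoref) -> tuple[float, float]:
    row, col = divmod(i, grid.ncols)
    return grid.cell_center(row, col)


def make_dataset(
    spec: SynthSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (sites, climate, truth) tables.

    Sites cycle through the zones; tnpp_obs is drawn as
    fraction * analytic tnpp_tmax * (1 + noise).  Each site has its own
    substream keyed by (seed, site index) so subsets reproduce.
    """
    grid = _site_grid(spec.n_sites)
    site_rows, climate_rows, truth_rows = [], [], []
    for i in range(spec.n_sites):
        zone = spec.zones[i % len(spec.zones)]
        rng = np.random.default_rng([spec.seed, i])
        climate = make_climate(zone, seed=None, jitter_sd=0.0)
        temp, srad = climate.temp, climate.srad
        if spec.climate_jitter_sd > 0:
            temp = temp + rng.normal(0.0, spec.climate_jitter_sd, 12)
            srad = np.maximum(
                srad + rng.normal(0.0, spec.climate_jitter_sd * 100.0, 12), 0.0
            )
        truth = analytic_truth(temp, srad, spec.co2_ppm)
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        tnpp_obs = zone.efit_fraction * truth["tnpp_tmax"] * (1.0 + noise)
        lon, lat = _site_lonlat(i, grid)
        site_id = f"S{i:04d}"
        site_rows.append(
            {
                "site_id": site_id,
                "lon": lon,
                "lat": lat,
                "year": spec.year,
                "tnpp_obs": tnpp_obs if tnpp_obs > 0 else np.nan,
                "climate_zone": zone.name,
                "phenology": zone.phenology,
            }
        )
        crow = {"site_id": site_id}
        crow.update({f"temp_{m + 1:02d}": temp[m] for m in range(12)})
        crow.update({f"srad_{m + 1:02d}": srad[m] for m in range(12)})
        climate_rows.append(crow)
        expected_efit = (
            100.0 * tnpp_obs / truth["tnpp_tmax"]
            if truth["tnpp_tmax"] > 0 and tnpp_obs > 0
            else np.nan
        )
        truth_rows.append(
            {
                "site_id": site_id,
                "zone": zone.name,
                **truth,
                "tnpp_obs": tnpp_obs,
                "efit": expected_efit,
            }
        )
    return (
        pd.DataFrame(site_rows),
        pd.DataFrame(climate_rows),
        pd.DataFrame(truth_rows),
    )


def write_dataset(
    spec: SynthSpec, out_dir: str | Path, rasters: bool = False
) -> dict[str, Path]:
    """Write sites.csv, climate.csv, co2.csv (and optional monthly GeoTIFF
    stacks laid out so point extraction reproduces climate.csv exactly)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites, climate, truth = make_dataset(spec)
    paths = {
        "sites": out / "sites.csv",
        "climate": out / "climate.csv",
        "truth": out / "truth.csv",
        "co2": out / "co2.csv",
    }
    sites.to_csv(paths["sites"], index=False)
    climate.to_csv(paths["climate"], index=False)
    truth.to_csv(paths["truth"], index=False)
    pd.DataFrame({"year": [spec.year], "ppm": [spec.co2_ppm]}).to_csv(
        paths["co2"], index=False
    )
    if rasters:
        grid = _site_grid(spec.n_sites)
        raster_dir = out / "rasters"
        raster_dir.mkdir(exist_ok=True)
        for var in ("temp", "srad"):
            for m in range(12):
                arr = np.full((grid.nrows, grid.ncols), -9999.0, dtype=np.float64)
                for i in range(spec.n_sites):
                    row, col = divmod(i, grid.ncols)
                    arr[row, col] = climate.iloc[i][f"{var}_{m + 1:02d}"]
                write_geotiff(
                    raster_dir / f"{var}_{m + 1:02d}.tif", arr, grid, nodata=-9999.0
                )
        paths["rasters"] = raster_dir
    return paths


def make_raster_stack(
    out_dir: str | Path,
    field_kind: str = "constant",
    value: float = 10.0,
    value_b: float = 20.0,
    grid: GridGeoref | None = None,
    nodata: float | None = None,
    prefix: str = "var",
) -> list[Path]:
    """Write 12 monthly rasters with a prescribed, closed-form field.

    ``field_kind``: 'constant' (every cell = value), 'lat_gradient'
    (cell value = its center latitude), or 'checkerboard' (alternating
    value/value_b, with NoData holes where (row + col) % 4 == 0 when a
    nodata value is given).
    """
    if grid is None:
        grid = GridGeoref(west=0.0, north=10.0, xres=1.0, yres=1.0, ncols=10, nrows=10)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = np.zeros((grid.nrows, grid.ncols), dtype=np.float32)
    for row in range(grid.nrows):
        for col in range(grid.ncols):
            if field_kind == "constant":
                arr[row, col] = value
            elif field_kind == "lat_gradient":
                arr[row, col] = grid.cell_center(row, col)[1]
            elif field_kind == "checkerboard":
                arr[row, col] = value if (row + col) % 2 == 0 else value_b
                if nodata is not None and (row + col) % 4 == 0:
                    arr[row, col] = nodata
            else:
                raise ValueError(f"unknown field_kind {field_kind!r}")
    paths = []
    for m in range(1, 13):
        path = out / f"{prefix}_{m:02d}.tif"
        write_geotiff(path, arr, grid, nodata=nodata)
        paths.append(path)
    return paths
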
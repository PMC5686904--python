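"""Environmental feature engineering for questing-tick counts.

Each tick observation (one transect, one sampling date) is characterised by
101 predictors in five blocks:

* H — 6 habitat descriptors of the transect (litter thickness and moss /
  herb / brush / tree covers on a 1-10 scale, plus a categorical habitat
  land-cover class),
* M — 9 mast-year scores (oak, American oak, beech x lags 0-2 years),
* W — 77 weather aggregates: 7 daily variables (minimum / maximum
  temperature, precipitation, reference evapotranspiration, relative
  humidity, saturation deficit, vapour pressure) averaged over 11 windows
  of {1..7, 14, 30, 90, 365} days strictly before the sampling date,
* V — 6 vegetation-index summaries (minimum and seasonal range of NDVI,
  EVI and NDWI), and
* L — 3 land-cover classes at 25 m, 500 m and 1 km resolution.

The country-level subset drops the H and M blocks (they exist only at the
monitored transects), leaving 86 predictors available for every forest
pixel.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import seasonal_decompose

from .io import NODATA

WEATHER_VARIABLES = ("tmin", "tmax", "prec", "ev", "rh", "sd", "vp")
WINDOWS = (1, 2, 3, 4, 5, 6, 7, 14, 30, 90, 365)

HABITAT_FEATURES = ("litter", "moss", "herb", "brush", "tree", "biolc")
MAST_SPECIES = ("oak", "aoak", "beech")
MAST_FEATURES = tuple(f"{sp}-{lag}" for lag in (0, 1, 2) for sp in MAST_SPECIES)
VEGETATION_INDICES = ("ndvi", "evi", "ndwi")
VEGETATION_FEATURES = tuple(
    f"{kind}_{idx}" for idx in VEGETATION_INDICES for kind in ("min", "range")
)
LANDCOVER_FEATURES = ("lc25m", "lc500m", "lc1km")
WEATHER_FEATURES = tuple(
    f"{var}-{w}" for w in WINDOWS for var in WEATHER_VARIABLES
)


class MissingDataError(ValueError):
    """An environmental input does not cover an observation."""


def feature_names(country_level: bool = False) -> list[str]:
    """Ordered predictor names; 101 in full mode, 86 at country level."""
    names: list[str] = []
    if not country_level:
        names += list(HABITAT_FEATURES)
        names += list(MAST_FEATURES)
    names += list(WEATHER_FEATURES)
    names += list(VEGETATION_FEATURES)
    names += list(LANDCOVER_FEATURES)
    return names


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

def saturation_vapour_pressure(temp_c):
    """Magnus formula over water: e_s(T) = 6.112 exp(17.62 T / (243.12 + T)) hPa."""
    temp_c = np.asarray(temp_c, dtype=float)
    return 6.112 * np.exp(17.62 * temp_c / (243.12 + temp_c))


def derive_humidity_vars(tmin, tmax, rh):
    """Saturation deficit and vapour pressure (hPa) from daily temperature and RH.

    The daily temperature is taken as the midpoint (tmin + tmax) / 2; vapour
    pressure is rh% of the Magnus saturation pressure at that temperature and
    the deficit is the remainder, so sd + vp == e_s(T) exactly.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    if np.any(rh <= 0) or np.any(rh > 100):
        raise ValueError("relative humidity must lie in (0, 100]")
    es = saturation_vapour_pressure((tmin + tmax) / 2.0)
    vp = rh / 100.0 * es
    sd = es - vp
    return sd, vp


def add_derived_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a daily weather frame with sd and vp columns added."""
    out = weather.copy()
    sd, vp = derive_humidity_vars(out["tmin"], out["tmax"], out["rh"])
    out["sd"] = sd
    out["vp"] = vp
    return out


def aggregate_weather(series: pd.DataFrame, sampling_date, window_days: int,
                      variable: str) -> float:
    """Mean of ``variable`` over the ``window_days`` days strictly before the date.

    The sampling day itself is excluded: the window is
    [date - window_days, date - 1].
    """
    if window_days not in WINDOWS:
        raise ValueError(f"window {window_days} not in the 11-window scheme")
    date = pd.Timestamp(sampling_date)
    idx = pd.date_range(date - pd.Timedelta(days=window_days),
                        date - pd.Timedelta(days=1), freq="D")
    try:
        values = series.loc[idx, variable]
    except KeyError:
        raise MissingDataError(
            f"weather series does not cover {window_days} days before "
            f"{date.date()} for variable {variable!r}")
    if values.isna().any():
        raise MissingDataError(
            f"missing daily values in the {window_days}-day window before "
            f"{date.date()} for variable {variable!r}")
    return float(values.mean())


def weather_feature_table(weather: pd.DataFrame,
                          dates: Iterable[pd.Timestamp]) -> pd.DataFrame:
    """All 77 window means for each requested sampling date.

    ``weather`` must be date-indexed, gap-free daily data with the 5 observed
    columns; sd and vp are derived here if absent. Uses shifted rolling means
    so the window ends the day before each date.
    """
    wx = weather.sort_index()
    if not {"sd", "vp"}.issubset(wx.columns):
        wx = add_derived_weather(wx)
    full = pd.date_range(wx.index.min(), wx.index.max(), freq="D")
    if len(full) != len(wx.index):
        raise MissingDataError("daily weather series has gaps")
    dates = pd.DatetimeIndex(dates)
    out = pd.DataFrame(index=dates)
    for w in WINDOWS:
        rolled = wx[list(WEATHER_VARIABLES)].rolling(w).mean().shift(1)
        block = rolled.reindex(dates)
        for var in WEATHER_VARIABLES:
            out[f"{var}-{w}"] = block[var]
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise MissingDataError(f"insufficient weather coverage for {bad[:4]}...")
    return out


# ---------------------------------------------------------------------------
# Vegetation
# ---------------------------------------------------------------------------

def vegetation_features(composites: pd.DataFrame) -> dict[str, float]:
    """Summaries of the seasonal cycle of vegetation-index composites.

    The 8-day composites are averaged per calendar month, the monthly series
    decomposed additively (period 12) into trend + seasonal + residual, and
    two numbers kept per index: the minimum of the seasonal cycle placed back
    on the series' mean level, and the seasonal range (max - min of the
    seasonal component).
    """
    monthly = composites.resample("MS").mean()
    if len(monthly) < 24:
        raise ValueError(
            f"need >= 24 monthly composites for seasonal decomposition, "
            f"got {len(monthly)}")
    out: dict[str, float] = {}
    cols = [c for c in VEGETATION_INDICES if c in composites.columns]
    if not cols:
        cols = list(composites.columns)
    for col in cols:
        series = monthly[col].astype(float)
        if series.isna().any():
            raise ValueError(f"vegetation series {col!r} has missing months")
        dec = seasonal_decompose(series, model="additive", period=12,
                                 extrapolate_trend="freq")
        seasonal = np.asarray(dec.seasonal, dtype=float)
        level = float(np.mean(dec.trend))
        out[f"min_{col}"] = float(level + seasonal.min())
        out[f"range_{col}"] = float(seasonal.max() - seasonal.min())
    return out


# ---------------------------------------------------------------------------
# Land cover
# ---------------------------------------------------------------------------

def reclassify_landcover(raster: np.ndarray, class_map: Mapping[int, int],
                         nodata: int = NODATA) -> np.ndarray:
    """Many-to-one reclassification of a categorical raster via a lookup map."""
    raster = np.asarray(raster)
    codes = np.unique(raster)
    codes = codes[codes != nodata]
    unmapped = [int(c) for c in codes if int(c) not in class_map]
    if unmapped:
        raise ValueError(f"unmapped land cover codes: {unmapped}")
    out = np.full_like(raster, nodata)
    for src, dst in class_map.items():
        out[raster == src] = dst
    out[raster == nodata] = nodata
    if len(np.unique(out[out != nodata])) > 12:
        raise ValueError("reclassified legend exceeds 12 classes")
    return out


def majority_resample(raster: np.ndarray, factor: int,
                      nodata: int = NODATA) -> np.ndarray:
    """Block-modal downsampling of a categorical raster.

    Each ``factor`` x ``factor`` block collapses to its most frequent class;
    ties break to the smallest class code and nodata cells do not vote.
    Rasters whose dimensions are not divisible by ``factor`` are padded with
    nodata.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    raster = np.asarray(raster)
    rows, cols = raster.shape
    pad_r = (-rows) % factor
    pad_c = (-cols) % factor
    if pad_r or pad_c:
        raster = np.pad(raster, ((0, pad_r), (0, pad_c)),
                        constant_values=nodata)
        rows, cols = raster.shape
    blocks = (raster.reshape(rows // factor, factor, cols // factor, factor)
              .transpose(0, 2, 1, 3)
              .reshape(-1, factor * factor))
    out = np.empty(blocks.shape[0], dtype=raster.dtype)
    for i, block in enumerate(blocks):
        votes = block[block != nodata]
        if votes.size == 0:
            out[i] = nodata
            continue
        shifted = votes - votes.min()
        counts = np.bincount(shifted)
        out[i] = votes.min() + int(np.argmax(counts))
    return out.reshape(rows // factor, cols // factor)


# ---------------------------------------------------------------------------
# Mast
# ---------------------------------------------------------------------------

def mast_features(mast: pd.DataFrame, year: int) -> dict[str, int]:
    """The 9 mast scores (3 species x lags 0-2 years) for an observation year."""
    table = mast.set_index(["species", "year"])["score"]
    out: dict[str, int] = {}
    for lag in (0, 1, 2):
        for sp in MAST_SPECIES:
            try:
                out[f"{sp}-{lag}"] = int(table.loc[(sp, year - lag)])
            except KeyError:
                raise MissingDataError(
                    f"no mast score for species {sp!r} in year {year - lag}")
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

KEY_COLUMNS = ("site", "transect", "date")


def assemble_features(obs: pd.DataFrame, world, country_level: bool = False,
                      ) -> pd.DataFrame:
    """Feature table for an observation table against a synthetic world.

    Returns one row per observation: the key columns (site, transect, date),
    any count/target columns present on ``obs``, then the predictors in
    canonical order (101 columns, or 86 when ``country_level``).
    """
    required = set(KEY_COLUMNS)
    if not required.issubset(obs.columns):
        raise ValueError(f"observation table must have columns {sorted(required)}")
    obs = obs.copy()
    obs["date"] = pd.to_datetime(obs["date"])
    names = feature_names(country_level)
    feats = pd.DataFrame(index=obs.index, columns=names, dtype=float)

    # weather block: one rolling pass per site
    for site, group in obs.groupby("site", sort=False):
        wx = add_derived_weather(world.weather[site])
        table = weather_feature_table(wx, group["date"])
        table.index = group.index
        feats.loc[group.index, list(table.columns)] = table

    # static per-transect blocks
    sites = world.sites.set_index(["site", "transect"])
    habitat = world.habitat.set_index(["site", "transect"])
    veg_cache: dict[tuple[str, str], dict[str, float]] = {}
    lc_cache: dict[tuple[int, int], dict[str, int]] = {}
    for (site, transect), group in obs.groupby(["site", "transect"], sort=False):
        key = (site, transect)
        try:
            row = sites.loc[key]
        except KeyError:
            raise MissingDataError(f"unknown transect {key}")
        r, c = int(row["row"]), int(row["col"])
        if key not in veg_cache:
            veg_cache[key] = vegetation_features(world.vegetation_series(r, c))
        for name, value in veg_cache[key].items():
            feats.loc[group.index, name] = value
        if (r, c) not in lc_cache:
            lc_cache[(r, c)] = landcover_values(world, r, c)
        for name, value in lc_cache[(r, c)].items():
            feats.loc[group.index, name] = value
        if not country_level:
            hab = habitat.loc[key]
            for name in HABITAT_FEATURES:
                feats.loc[group.index, name] = float(hab[name])

    if not country_level:
        for year, group in obs.groupby(obs["date"].dt.year, sort=False):
            scores = mast_features(world.mast, int(year))
            for name, value in scores.items():
                feats.loc[group.index, name] = value

    if feats.isna().any().any():
        bad = feats.columns[feats.isna().any()].tolist()
        raise MissingDataError(f"unresolved features: {bad[:5]}")
    carried = [c for c in obs.columns if c not in names]
    return pd.concat([obs[carried], feats], axis=1)


def landcover_values(world, row: int, col: int) -> dict[str, int]:
    """The three-resolution land-cover codes for a 500 m grid cell."""
    f = world.native_factor
    native_code = int(world.landcover_native[row * f + f // 2,
                                             col * f + f // 2])
    lc25 = int(world.class_map[native_code])
    lc500 = int(world.landcover_500m[row, col])
    lc1km = int(world.landcover_1km[row // 2, col // 2])
    return {"lc25m": lc25, "lc500m": lc500, "lc1km": lc1km}
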
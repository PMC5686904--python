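"""Country-wide daily prediction of questing-tick activity.

Forest pixels are extracted from the 12-class land-cover map (deciduous,
coniferous and mixed forest), the 86 country-level features are built for
every forest pixel and every day of a target year, and a model retrained on
those features predicts a daily activity surface. Products: the annual
per-pixel mean and standard deviation, single-date maps, and daily activity
profiles at the monitoring-site pixels.

Weather at an arbitrary pixel comes from the synthetic world's regional
field (regional daily series plus the spatial gradient); vegetation
summaries exploit the generator's structure — a pixel's composite series is
the regional series shifted by a constant level, which shifts the seasonal
minimum by the same constant and leaves the range unchanged — falling back
to an explicit per-pixel decomposition wherever the [-1, 1] clip binds.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (MissingDataError, WEATHER_VARIABLES, WINDOWS,
                       derive_humidity_vars, feature_names,
                       vegetation_features)
from .io import GridMeta, NODATA, write_ascii_grid
from .model import MONTH_COLUMN, ModelConfig, TimeAwareForestRegressor
from .preprocessing import PreparedDataset
from .synthetic import FOREST_CLASSES, LANDCOVER_CLASSES, _gradient_offset

COUNTRY_FEATURES = feature_names(country_level=True)


def forest_mask(landcover12: np.ndarray, nodata: int = NODATA) -> np.ndarray:
    """True where the 12-class raster holds a forest class."""
    raster = np.asarray(landcover12)
    codes = set(np.unique(raster).tolist()) - {nodata}
    known = set(LANDCOVER_CLASSES.values())
    if not codes.issubset(known):
        raise ValueError(f"unknown land cover codes: {sorted(codes - known)}")
    return np.isin(raster, list(FOREST_CLASSES))


# ---------------------------------------------------------------------------
# per-pixel feature construction
# ---------------------------------------------------------------------------

def _pixel_daily_weather(world, rows: np.ndarray, cols: np.ndarray,
                         day_index: pd.DatetimeIndex) -> dict[str, np.ndarray]:
    """Daily matrices (n_days x n_pixels) of the 7 weather variables."""
    regional = world.weather_regional
    if (day_index.min() < regional.index.min()
            or day_index.max() > regional.index.max()):
        raise MissingDataError(
            f"regional weather does not cover {day_index.min().date()} .. "
            f"{day_index.max().date()}")
    reg = regional.reindex(day_index)
    grid = world.config.grid_shape
    off = {v: np.array([_gradient_offset(v, r, c, grid)
                        for r, c in zip(rows, cols)])
           for v in ("tmid", "trange", "prec", "ev", "rh")}
    tmid = reg["tmid"].to_numpy()[:, None] + off["tmid"][None, :]
    trange = np.maximum(
        reg["trange"].to_numpy()[:, None] + off["trange"][None, :], 0.5)
    out = {
        "tmin": tmid - trange / 2.0,
        "tmax": tmid + trange / 2.0,
        "prec": np.maximum(
            reg["prec"].to_numpy()[:, None] + off["prec"][None, :], 0.0),
        "ev": np.maximum(
            reg["ev"].to_numpy()[:, None] + off["ev"][None, :], 0.05),
        "rh": np.clip(
            reg["rh"].to_numpy()[:, None] + off["rh"][None, :], 5.0, 100.0),
    }
    out["sd"], out["vp"] = derive_humidity_vars(out["tmin"], out["tmax"],
                                                out["rh"])
    return out


class CountryFeatureBuilder:
    """Builds 86-column feature frames for forest pixels, any date.

    Static blocks (vegetation summaries, land-cover codes) are computed once;
    weather window means come from cumulative sums over a daily span wide
    enough for the 365-day window before every requested date.
    """

    def __init__(self, world, mask: np.ndarray,
                 dates: pd.DatetimeIndex | None = None):
        self.world = world
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != world.landcover_500m.shape:
            raise ValueError("mask shape does not match the land cover grid")
        pix = np.argwhere(self.mask)
        self.rows = pix[:, 0]
        self.cols = pix[:, 1]
        if dates is None:
            dates = world.weather_regional.index[365:]
        dates = pd.DatetimeIndex(dates)
        self.day_index = pd.date_range(dates.min() - pd.Timedelta(days=365),
                                       dates.max() - pd.Timedelta(days=1),
                                       freq="D")
        daily = _pixel_daily_weather(world, self.rows, self.cols,
                                     self.day_index)
        self._csum = {v: np.vstack([np.zeros((1, len(self.rows))),
                                    np.cumsum(m, axis=0)])
                      for v, m in daily.items()}
        self._static = self._static_block()

    # -- static blocks ----------------------------------------------------
    def _static_block(self) -> pd.DataFrame:
        world = self.world
        veg_reg = vegetation_features(world.veg_regional)
        static = pd.DataFrame(index=range(len(self.rows)))
        reg = world.veg_regional
        for idx in ("ndvi", "evi", "ndwi"):
            offsets = world.veg_offsets[idx][self.rows, self.cols]
            lo = reg[idx].min() + offsets
            hi = reg[idx].max() + offsets
            clipped = (lo < -1.0) | (hi > 1.0)
            static[f"min_{idx}"] = veg_reg[f"min_{idx}"] + offsets
            static[f"range_{idx}"] = veg_reg[f"range_{idx}"]
            for i in np.nonzero(clipped)[0]:
                exact = vegetation_features(
                    world.vegetation_series(int(self.rows[i]),
                                            int(self.cols[i])))
                static.loc[i, f"min_{idx}"] = exact[f"min_{idx}"]
                static.loc[i, f"range_{idx}"] = exact[f"range_{idx}"]
        f = world.native_factor
        centers = (self.rows * f + f // 2, self.cols * f + f // 2)
        native_codes = world.landcover_native[centers]
        static["lc25m"] = [world.class_map[int(c)] for c in native_codes]
        static["lc500m"] = world.landcover_500m[self.rows, self.cols]
        static["lc1km"] = world.landcover_1km[self.rows // 2, self.cols // 2]
        return static

    # -- per-date frame ---------------------------------------------------
    def frame_for(self, date) -> pd.DataFrame:
        """The 86-column country feature table for one prediction date."""
        date = pd.Timestamp(date)
        i = self.day_index.get_indexer([date - pd.Timedelta(days=1)])[0]
        if i < 0:
            raise MissingDataError(f"date {date.date()} outside prepared span")
        i += 1  # csum position of the day before `date`, exclusive end
        if i - 365 < 0:
            raise MissingDataError(f"no 365-day coverage before {date.date()}")
        frame = pd.DataFrame(index=range(len(self.rows)))
        for w in WINDOWS:
            for var in WEATHER_VARIABLES:
                s = self._csum[var]
                frame[f"{var}-{w}"] = (s[i] - s[i - w]) / w
        for col in self._static.columns:
            frame[col] = self._static[col]
        return frame[COUNTRY_FEATURES]


def build_daily_country_features(world, date, mask: np.ndarray) -> pd.DataFrame:
    """One row per forest pixel with the 86 country-level features for ``date``."""
    builder = CountryFeatureBuilder(world, mask,
                                    dates=pd.DatetimeIndex([pd.Timestamp(date)]))
    frame = builder.frame_for(date)
    frame.index = pd.MultiIndex.from_arrays([builder.rows, builder.cols],
                                            names=["row", "col"])
    return frame


# ---------------------------------------------------------------------------
# retraining and yearly prediction
# ---------------------------------------------------------------------------

def retrain_country_model(dataset: PreparedDataset, world,
                          config: ModelConfig = ModelConfig(),
                          ) -> TimeAwareForestRegressor:
    """Fit the 86-feature model on the full dataset (train + test)."""
    from .features import assemble_features
    table = assemble_features(dataset.frame, world, country_level=True)
    X = table[COUNTRY_FEATURES].copy()
    X[MONTH_COLUMN] = pd.to_datetime(table["date"]).dt.month
    est = TimeAwareForestRegressor(
        n_estimators=config.n_trees, max_features=config.features_per_split,
        clip_predictions=True, n_jobs=config.n_jobs,
        random_state=config.run_seed)
    est.fit(X, table["target"].to_numpy(dtype=float))
    return est


@dataclass
class AnnualSummary:
    """Annual statistics of the daily prediction stack."""

    year: int
    mean: np.ndarray                     # grid; NODATA outside the mask
    sd: np.ndarray
    mask: np.ndarray
    site_profiles: pd.DataFrame          # site, date, aqt_pred, monthly_mu
    daily: dict[pd.Timestamp, np.ndarray] = dc_field(default_factory=dict)

    def daily_map(self, date) -> np.ndarray:
        return self.daily[pd.Timestamp(date)]


def predict_year(est: TimeAwareForestRegressor, world, year: int,
                 mask: np.ndarray | None = None,
                 keep_dates: tuple = (), keep_daily: bool = False,
                 ) -> AnnualSummary:
    """Daily country predictions for a calendar year.

    Predicts the year's actual day count (366 in leap years), de-normalizes
    with each date's calendar month (clipped at zero), and accumulates the
    per-pixel annual mean and population standard deviation. Rasters carry
    NODATA outside the forest mask.
    """
    if mask is None:
        mask = forest_mask(world.landcover_500m)
    n_days = 366 if calendar.isleap(year) else 365
    dates = pd.date_range(f"{year}-01-01", periods=n_days, freq="D")
    builder = CountryFeatureBuilder(world, mask, dates=dates)
    n_pix = len(builder.rows)

    site_pixels = {}
    for site, group in world.sites.groupby("site", sort=True):
        r, c = int(group["row"].iloc[0]), int(group["col"].iloc[0])
        hits = np.nonzero((builder.rows == r) & (builder.cols == c))[0]
        if hits.size:
            site_pixels[site] = int(hits[0])

    keep = {pd.Timestamp(d) for d in keep_dates}
    total = np.zeros(n_pix)
    total_sq = np.zeros(n_pix)
    daily_kept: dict[pd.Timestamp, np.ndarray] = {}
    profile_rows = []
    norm = est.normalization_
    for date in dates:
        X = builder.frame_for(date)
        X[MONTH_COLUMN] = date.month
        pred = np.maximum(est.predict(X), 0.0)
        total += pred
        total_sq += pred ** 2
        if keep_daily or date in keep:
            daily_kept[date] = _rasterize(pred, builder, mask)
        for site, j in site_pixels.items():
            profile_rows.append({
                "site": site, "date": date, "aqt_pred": float(pred[j]),
                "monthly_mu": float(norm.mu[date.month - 1])})

    mean = total / n_days
    var = np.maximum(total_sq / n_days - mean ** 2, 0.0)
    return AnnualSummary(
        year=year,
        mean=_rasterize(mean, builder, mask),
        sd=_rasterize(np.sqrt(var), builder, mask),
        mask=mask,
        site_profiles=pd.DataFrame(profile_rows),
        daily=daily_kept)


def _rasterize(values: np.ndarray, builder: CountryFeatureBuilder,
               mask: np.ndarray) -> np.ndarray:
    grid = np.full(mask.shape, float(NODATA))
    grid[builder.rows, builder.cols] = values
    return grid


def write_annual_summary(summary: AnnualSummary, out_dir: str | Path,
                         cellsize: float = 500.0) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = GridMeta(cellsize=cellsize)
    write_ascii_grid(out / f"aqt_mean_{summary.year}.asc", summary.mean, meta,
                     fmt="%.4f")
    write_ascii_grid(out / f"aqt_sd_{summary.year}.asc", summary.sd, meta,
                     fmt="%.4f")
    for date, grid in summary.daily.items():
        write_ascii_grid(out / f"aqt_{date.strftime('%Y%m%d')}.asc", grid,
                         meta, fmt="%.4f")
    summary.site_profiles.to_csv(out / f"site_profiles_{summary.year}.csv",
                                 index=False)
    return out
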
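"""Synthetic study system for volunteer tick monitoring.

Generates a self-contained world — a gridded landscape, daily weather
fields, vegetation-index composites, a categorical land-cover map, mast
scores and transect habitat descriptors — together with monthly counts of
active questing ticks (AQT) whose drivers are known. The generator mimics
the statistical character of the real monitoring scheme (a small, weather-
uniform country; monthly volunteer drag sampling on paired forest
transects; over-dispersed counts with roughly one third zeros and
occasional peaks) without reproducing any real geography.

Counts follow a negative-binomial law on a log link: the latent
log-activity is an annual sinusoid (tick phenology) plus a weighted sum of
standardized lagged-weather anomalies — the configurable ground truth that
downstream feature-importance analyses are expected to recover — and an
independent Bernoulli mask adds structural zeros on top.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import (WEATHER_VARIABLES, WINDOWS, add_derived_weather,
                       majority_resample, reclassify_landcover,
                       weather_feature_table)
from .io import GridMeta, read_ascii_grid, write_ascii_grid

# ---------------------------------------------------------------------------
# Land cover legends
# ---------------------------------------------------------------------------

#: target 12-class legend
LANDCOVER_CLASSES = {
    "deciduous_forest": 1,
    "coniferous_forest": 2,
    "mixed_forest": 3,
    "grassland": 4,
    "heathland": 5,
    "bushland": 6,
    "agriculture": 7,
    "urban": 8,
    "water": 9,
    "dunes_sand": 10,
    "wetland": 11,
    "other": 12,
}
FOREST_CLASSES = frozenset((1, 2, 3))

#: synthetic source legend (LGN-like, 30 codes) collapsed onto the 12 classes
DEFAULT_CLASS_MAP = {
    1: 7, 2: 7, 3: 7, 4: 7, 5: 7, 6: 7, 7: 7,        # crop types -> agriculture
    8: 4, 9: 4,                                       # grass types -> grassland
    10: 1, 11: 1,                                     # deciduous variants
    12: 2, 13: 2,                                     # coniferous variants
    14: 3,                                            # mixed forest
    15: 5, 16: 5,                                     # heath variants
    17: 6, 18: 6,                                     # shrub/scrub -> bushland
    19: 8, 20: 8, 21: 8,                              # built-up & roads -> urban
    22: 9, 23: 9,                                     # fresh/salt water
    24: 10, 25: 10,                                   # dunes & beach
    26: 11, 27: 11,                                   # marsh & bog -> wetland
    28: 12, 29: 12, 30: 12,                           # bare/greenhouse/other
}
_SOURCE_CODES = np.array(sorted(DEFAULT_CLASS_MAP))
_SOURCE_PROBS = np.array([
    0.020, 0.020, 0.020, 0.020, 0.020, 0.015, 0.015,   # agriculture 13%
    0.090, 0.090,                                      # grassland 18%
    0.100, 0.080,                                      # deciduous 18%
    0.055, 0.045,                                      # coniferous 10%
    0.060,                                             # mixed 6%
    0.025, 0.020,                                      # heath
    0.025, 0.020,                                      # bush
    0.030, 0.025, 0.015,                               # urban
    0.035, 0.020,                                      # water
    0.020, 0.015,                                      # dunes
    0.025, 0.020,                                      # wetland
    0.020, 0.015, 0.020,                               # other
])
assert abs(_SOURCE_PROBS.sum() - 1.0) < 1e-9

# ---------------------------------------------------------------------------
# Weather / vegetation climatology (annual sinusoids; module constants so the
# deterministic expectation is recomputable anywhere)
# ---------------------------------------------------------------------------

YEAR_DAYS = 365.25

#: var -> (annual mean, amplitude, day-of-year of the peak)
SEASONAL = {
    "tmid": (10.0, 7.5, 200.0),
    "trange": (8.0, 2.0, 200.0),
    "prec": (2.2, 0.8, 220.0),
    "ev": (1.5, 1.25, 180.0),
    "rh": (82.0, -8.0, 180.0),   # negative amplitude: driest in summer
    "ndvi": (0.55, 0.25, 190.0),
    "evi": (0.35, 0.20, 190.0),
    "ndwi": (0.10, 0.18, 200.0),
}
#: regional AR(1) weather noise: var -> (sigma, rho)
NOISE = {
    "tmid": (2.2, 0.80),
    "trange": (1.2, 0.50),
    "prec": (1.8, 0.30),
    "ev": (0.45, 0.70),
    "rh": (6.0, 0.75),
}
#: per-site microclimate AR(1) sigma (rho 0.5); adds transect-scale texture
MICRO_SIGMA = {"tmid": 0.5, "trange": 0.3, "prec": 0.5, "ev": 0.12, "rh": 2.0}
#: spatial gradients across the full grid extent: var -> (row span, col span)
GRADIENTS = {
    "tmid": (-1.5, 0.5),
    "trange": (0.0, 0.0),
    "prec": (0.6, 0.0),
    "ev": (0.35, 0.10),
    "rh": (5.0, -1.0),
    "ndvi": (0.05, 0.00),
    "evi": (0.04, 0.00),
    "ndwi": (0.05, 0.00),
}

#: latent AQT phenology: log-activity = BASE + AMP * cos(doy peak at PEAK_DOY)
BASELINE_LOG = 3.0
BASELINE_AMP = 1.0
BASELINE_PEAK_DOY = 150.0

NATIVE_PIXEL_M = 25.0


class ConfigError(ValueError):
    """A world configuration field is invalid."""


@dataclass(frozen=True)
class WorldConfig:
    """Design of the synthetic study.

    ``driver_weights`` maps weather features (``"<var>-<window>"``, e.g.
    ``"ev-365"``) to effect sizes on the latent log-activity, in units of
    one standard deviation of that feature's anomaly. ``dispersion`` is the
    negative-binomial size parameter k (var = mu + mu^2 / k; ``inf`` gives
    Poisson counts) and ``zero_inflation`` the probability of masking a
    count to zero.
    """

    n_sites: int = 15
    transects_per_site: int = 2
    years: tuple[int, int] = (2006, 2014)
    weather_start: str = "2005-01-01"
    grid_shape: tuple[int, int] = (60, 60)
    pixel_size: float = 500.0
    driver_weights: dict[str, float] = field(
        default_factory=lambda: {"ev-365": 0.6, "rh-30": 0.45})
    dispersion: float = 6.0
    zero_inflation: float = 0.33
    seed: int = 42

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.transects_per_site < 1:
            raise ConfigError("transects_per_site must be >= 1")
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigError("years range is inverted")
        first_sampling = pd.Timestamp(year=y0, month=1, day=1)
        if pd.Timestamp(self.weather_start) > first_sampling - pd.Timedelta(days=365):
            raise ConfigError(
                "weather_start must precede the first sampling year by >= 365 "
                "days (the 365-day aggregation window)")
        rows, cols = self.grid_shape
        if rows < 3 or cols < self.transects_per_site + 2:
            raise ConfigError("grid_shape too small for site placement")
        if self.n_sites * 3 * (self.transects_per_site + 1) > rows * cols:
            raise ConfigError("grid_shape too small for n_sites")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ConfigError("zero_inflation must lie in [0, 1]")
        if not self.dispersion > 0:
            raise ConfigError("dispersion must be positive")
        for key in self.driver_weights:
            var, _, win = key.partition("-")
            if var not in WEATHER_VARIABLES or not win.isdigit() \
                    or int(win) not in WINDOWS:
                raise ConfigError(
                    f"driver_weights key {key!r} is not a (variable, window) "
                    f"pair from the 11-window scheme")

    @property
    def native_factor(self) -> int:
        return max(1, int(round(self.pixel_size / NATIVE_PIXEL_M)))

    @property
    def weather_end(self) -> pd.Timestamp:
        return pd.Timestamp(year=self.years[1], month=12, day=31)


@dataclass
class SyntheticWorld:
    """Generated landscape, environment and ground truth."""

    config: WorldConfig
    sites: pd.DataFrame                   # site, transect, row, col
    weather: dict[str, pd.DataFrame]      # per site: daily tmin..rh
    weather_regional: pd.DataFrame        # daily tmid/trange/prec/ev/rh + noise
    habitat: pd.DataFrame
    mast: pd.DataFrame
    veg_regional: pd.DataFrame            # 8-day ndvi/evi/ndwi series
    veg_offsets: dict[str, np.ndarray]    # per index: grid of level offsets
    landcover_native: np.ndarray          # source legend, native resolution
    landcover_native12: np.ndarray        # reclassified, native resolution
    landcover_500m: np.ndarray
    landcover_1km: np.ndarray
    class_map: dict[int, int]
    truth: dict

    @property
    def native_factor(self) -> int:
        return self.config.native_factor

    def vegetation_series(self, row: int, col: int) -> pd.DataFrame:
        """8-day composite series of the three indices at one 500 m cell."""
        out = self.veg_regional.copy()
        for idx in ("ndvi", "evi", "ndwi"):
            out[idx] = np.clip(out[idx] + self.veg_offsets[idx][row, col],
                               -1.0, 1.0)
        return out

    def pixel_weather(self, row: int, col: int) -> pd.DataFrame:
        """Daily observed weather at one grid cell of the regional field."""
        offsets = {v: _gradient_offset(v, row, col, self.config.grid_shape)
                   for v in NOISE}
        return _assemble_weather(self.weather_regional, offsets)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _seasonal_curve(var: str, dates: pd.DatetimeIndex) -> np.ndarray:
    mean, amp, peak = SEASONAL[var]
    doy = dates.dayofyear.to_numpy(dtype=float)
    return mean + amp * np.cos(2 * np.pi * (doy - peak) / YEAR_DAYS)


def _ar1(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    eps = rng.normal(scale=sigma * np.sqrt(1 - rho ** 2), size=n)
    out = np.empty(n)
    prev = rng.normal(scale=sigma)
    for i in range(n):
        prev = rho * prev + eps[i]
        out[i] = prev
    return out


def _gradient_offset(var: str, row, col, grid_shape) -> float:
    g_r, g_c = GRADIENTS[var]
    rows, cols = grid_shape
    fr = (row / (rows - 1) - 0.5) if rows > 1 else 0.0
    fc = (col / (cols - 1) - 0.5) if cols > 1 else 0.0
    return g_r * fr + g_c * fc


def _assemble_weather(regional: pd.DataFrame,
                      offsets: dict[str, float],
                      micro: pd.DataFrame | None = None) -> pd.DataFrame:
    """Combine regional series, a location offset and optional micro noise
    into the observed daily variables, applying physical bounds."""
    parts = {}
    for var in ("tmid", "trange", "prec", "ev", "rh"):
        x = regional[var].to_numpy() + offsets.get(var, 0.0)
        if micro is not None:
            x = x + micro[var].to_numpy()
        parts[var] = x
    trange = np.maximum(parts["trange"], 0.5)
    out = pd.DataFrame({
        "tmin": parts["tmid"] - trange / 2.0,
        "tmax": parts["tmid"] + trange / 2.0,
        "prec": np.maximum(parts["prec"], 0.0),
        "ev": np.maximum(parts["ev"], 0.05),
        "rh": np.clip(parts["rh"], 5.0, 100.0),
    }, index=regional.index)
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig = WorldConfig()) -> SyntheticWorld:
    """Generate a world deterministically from ``config.seed``."""
    config.validate()
    rows, cols = config.grid_shape
    dates = pd.date_range(config.weather_start, config.weather_end, freq="D")

    # regional weather: seasonal sinusoid + AR(1) anomaly, shared by all sites
    rng_wx = np.random.default_rng([config.seed, 0])
    regional = pd.DataFrame(index=dates)
    for var in ("tmid", "trange", "prec", "ev", "rh"):
        sigma, rho = NOISE[var]
        regional[var] = _seasonal_curve(var, dates) + _ar1(
            rng_wx, len(dates), sigma, rho)

    # site / transect placement: clusters of adjacent 500 m cells
    rng_sites = np.random.default_rng([config.seed, 1])
    k = config.transects_per_site
    taken: set[tuple[int, int]] = set()
    site_rows = []
    for s in range(config.n_sites):
        for _ in range(10_000):
            r = int(rng_sites.integers(1, rows - 1))
            c = int(rng_sites.integers(1, cols - k))
            cells = [(r, c + j) for j in range(k)]
            if not any(cell in taken for cell in cells):
                taken.update(cells)
                break
        else:
            raise ConfigError("could not place sites on the grid")
        for j, (rr, cc) in enumerate(cells):
            site_rows.append({"site": f"s{s + 1:02d}",
                              "transect": chr(ord("a") + j),
                              "row": rr, "col": cc})
    sites = pd.DataFrame(site_rows)

    # per-site observed weather = regional + gradient offset + micro AR(1)
    weather: dict[str, pd.DataFrame] = {}
    rng_micro = np.random.default_rng([config.seed, 2])
    for site, group in sites.groupby("site", sort=True):
        r, c = int(group["row"].iloc[0]), int(group["col"].iloc[0])
        offsets = {v: _gradient_offset(v, r, c, config.grid_shape)
                   for v in NOISE}
        micro = pd.DataFrame(
            {v: _ar1(rng_micro, len(dates), MICRO_SIGMA[v], 0.5)
             for v in NOISE}, index=dates)
        weather[site] = _assemble_weather(regional, offsets, micro)

    # land cover: patchwork of source classes at the 500 m cell level,
    # upsampled to native resolution with salt noise; site cells forced to a
    # deciduous source class so every transect sits in forest
    rng_lc = np.random.default_rng([config.seed, 3])
    factor = config.native_factor
    patches = rng_lc.choice(_SOURCE_CODES, size=(rows, cols), p=_SOURCE_PROBS)
    for rr, cc in taken:
        patches[rr, cc] = 10  # deciduous source code
    native = np.kron(patches, np.ones((factor, factor), dtype=int))
    noise_mask = rng_lc.random(native.shape) < 0.15
    protected = np.zeros((rows, cols), dtype=bool)
    for rr, cc in taken:
        protected[rr, cc] = True
    noise_mask &= ~np.kron(protected, np.ones((factor, factor), dtype=bool))
    native[noise_mask] = rng_lc.choice(_SOURCE_CODES, size=int(noise_mask.sum()),
                                       p=_SOURCE_PROBS)
    native12 = reclassify_landcover(native, DEFAULT_CLASS_MAP)
    lc500 = majority_resample(native12, factor)
    lc1km = majority_resample(lc500, 2)

    # vegetation: regional 8-day composites + smooth spatial level offsets
    rng_veg = np.random.default_rng([config.seed, 4])
    veg_dates = pd.date_range(config.weather_start, config.weather_end,
                              freq="8D")
    veg_regional = pd.DataFrame(index=veg_dates)
    for idx in ("ndvi", "evi", "ndwi"):
        veg_regional[idx] = np.clip(
            _seasonal_curve(idx, veg_dates)
            + rng_veg.normal(scale=0.02, size=len(veg_dates)), -1.0, 1.0)
    veg_offsets = {}
    for idx in ("ndvi", "evi", "ndwi"):
        rr = (np.arange(rows) / max(rows - 1, 1) - 0.5)[:, None]
        cc = (np.arange(cols) / max(cols - 1, 1) - 0.5)[None, :]
        g_r, g_c = GRADIENTS[idx]
        field_noise = rng_veg.normal(scale=0.02, size=(rows, cols))
        veg_offsets[idx] = g_r * rr + g_c * cc + field_noise

    # mast scores: ordinal 0-5 per species-year, two years of pre-history
    rng_mast = np.random.default_rng([config.seed, 5])
    mast_years = range(config.years[0] - 2, config.years[1] + 1)
    mast = pd.DataFrame(
        [{"species": sp, "year": y,
          "score": int(rng_mast.integers(0, 6))}
         for sp in ("oak", "aoak", "beech") for y in mast_years])

    # habitat descriptors per transect
    rng_hab = np.random.default_rng([config.seed, 6])
    hab_rows = []
    for _, row in sites.iterrows():
        hab_rows.append({
            "site": row["site"], "transect": row["transect"],
            "litter": int(rng_hab.integers(1, 11)),
            "moss": int(rng_hab.integers(1, 11)),
            "herb": int(rng_hab.integers(1, 11)),
            "brush": int(rng_hab.integers(1, 11)),
            "tree": int(rng_hab.integers(1, 11)),
            "biolc": int(native12[row["row"] * factor + factor // 2,
                                  row["col"] * factor + factor // 2]),
        })
    habitat = pd.DataFrame(hab_rows)

    truth = {
        "driver_weights": dict(config.driver_weights),
        "baseline": {"log_level": BASELINE_LOG, "amplitude": BASELINE_AMP,
                     "peak_doy": BASELINE_PEAK_DOY},
    }
    return SyntheticWorld(
        config=config, sites=sites, weather=weather,
        weather_regional=regional, habitat=habitat, mast=mast,
        veg_regional=veg_regional, veg_offsets=veg_offsets,
        landcover_native=native, landcover_native12=native12,
        landcover_500m=lc500, landcover_1km=lc1km,
        class_map=dict(DEFAULT_CLASS_MAP), truth=truth)


def deterministic_regional_weather(dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Noise-free regional expectation of the observed weather variables."""
    det = pd.DataFrame(index=dates)
    for var in ("tmid", "trange", "prec", "ev", "rh"):
        det[var] = _seasonal_curve(var, dates)
    return _assemble_weather(det, {})


def generate_observations(world: SyntheticWorld,
                          config: WorldConfig | None = None,
                          return_latent: bool = False) -> pd.DataFrame:
    """Monthly AQT counts for every transect over the configured years.

    One observation per transect per calendar month; both transects of a
    site share the sampling day (drawn uniformly within the month). The
    returned frame carries the realized zero fraction in
    ``result.attrs["zero_fraction"]``; with ``return_latent`` the latent
    mean ``mu`` and log-activity are included as columns.
    """
    config = config or world.config
    rng_day = np.random.default_rng([config.seed, 10])
    rng_count = np.random.default_rng([config.seed, 11])
    y0, y1 = config.years

    rows = []
    for site, group in world.sites.groupby("site", sort=True):
        for year in range(y0, y1 + 1):
            for month in range(1, 13):
                ndays = calendar.monthrange(year, month)[1]
                day = int(rng_day.integers(1, ndays + 1))
                date = pd.Timestamp(year=year, month=month, day=day)
                for transect in group["transect"]:
                    rows.append({"site": site, "transect": transect,
                                 "date": date})
    obs = pd.DataFrame(rows)

    # driver anomalies: site window means minus the deterministic regional
    # expectation, standardized across the sample
    latent = np.full(len(obs), BASELINE_LOG, dtype=float)
    doy = obs["date"].dt.dayofyear.to_numpy(dtype=float)
    latent += BASELINE_AMP * np.cos(
        2 * np.pi * (doy - BASELINE_PEAK_DOY) / YEAR_DAYS)

    if config.driver_weights:
        # anomaly = the site's actual window mean minus the regional
        # seasonal expectation: it carries both the site's persistent
        # weather offset and the temporal fluctuations, so a persistently
        # wetter site is genuinely more active
        det = add_derived_weather(
            deterministic_regional_weather(world.weather_regional.index))
        det_feats = weather_feature_table(det, pd.DatetimeIndex(obs["date"]
                                                                .unique()))
        anomalies = pd.DataFrame(index=obs.index,
                                 columns=list(config.driver_weights), dtype=float)
        for site, group in obs.groupby("site", sort=False):
            wx = add_derived_weather(world.weather[site])
            site_feats = weather_feature_table(wx, group["date"])
            for key in config.driver_weights:
                det_vals = det_feats.loc[group["date"], key].to_numpy()
                anomalies.loc[group.index, key] = (
                    site_feats[key].to_numpy() - det_vals)
        for key, weight in config.driver_weights.items():
            a = anomalies[key].to_numpy(dtype=float)
            scale = a.std()
            z = (a - a.mean()) / (scale if scale > 0 else 1.0)
            latent += weight * z

    mu = np.minimum(np.exp(latent), 2000.0)
    if np.isinf(config.dispersion):
        counts = rng_count.poisson(mu)
    else:
        k = config.dispersion
        counts = rng_count.negative_binomial(k, k / (k + mu))
    mask = rng_count.random(len(obs)) < config.zero_inflation
    counts = np.where(mask, 0, counts)

    obs["aqt_count"] = counts.astype(int)
    if return_latent:
        obs["latent"] = latent
        obs["mu"] = mu
    obs.attrs["zero_fraction"] = float(np.mean(counts == 0))
    return obs


# ---------------------------------------------------------------------------
# persistence (all plain text: CSV, ASCII grid, YAML)
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = world.config
    meta500 = GridMeta(cellsize=cfg.pixel_size)
    meta25 = GridMeta(cellsize=NATIVE_PIXEL_M)
    meta1km = GridMeta(cellsize=cfg.pixel_size * 2)

    world.sites.to_csv(out / "sites.csv", index=False)
    world.habitat.to_csv(out / "habitat.csv", index=False)
    world.mast.to_csv(out / "mast.csv", index=False)
    world.weather_regional.to_csv(out / "weather_regional.csv",
                                  index_label="date", float_format="%.6f")
    for site, df in world.weather.items():
        df.to_csv(out / f"weather_{site}.csv", index_label="date",
                  float_format="%.6f")
    world.veg_regional.to_csv(out / "vegetation.csv", index_label="date",
                              float_format="%.6f")
    for idx, grid in world.veg_offsets.items():
        write_ascii_grid(out / f"veg_offset_{idx}.asc", grid, meta500,
                         fmt="%.6f")
    write_ascii_grid(out / "landcover_source.asc", world.landcover_native,
                     meta25)
    write_ascii_grid(out / "landcover_25m.asc", world.landcover_native12,
                     meta25)
    write_ascii_grid(out / "landcover_500m.asc", world.landcover_500m, meta500)
    write_ascii_grid(out / "landcover_1km.asc", world.landcover_1km, meta1km)

    cfg_dict = {
        "n_sites": cfg.n_sites, "transects_per_site": cfg.transects_per_site,
        "years": list(cfg.years), "weather_start": str(cfg.weather_start),
        "grid_shape": list(cfg.grid_shape), "pixel_size": cfg.pixel_size,
        "driver_weights": dict(cfg.driver_weights),
        "dispersion": float(cfg.dispersion),
        "zero_inflation": cfg.zero_inflation, "seed": cfg.seed,
    }
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump({"config": cfg_dict, "truth": world.truth,
                        "class_map": {int(k): int(v)
                                      for k, v in world.class_map.items()}},
                       fh, sort_keys=False)
    return out


def read_world(world_dir: str | Path) -> SyntheticWorld:
    src = Path(world_dir)
    with open(src / "truth.yaml") as fh:
        blob = yaml.safe_load(fh)
    cfg_dict = blob["config"]
    cfg_dict["years"] = tuple(cfg_dict["years"])
    cfg_dict["grid_shape"] = tuple(cfg_dict["grid_shape"])
    config = WorldConfig(**cfg_dict)

    sites = pd.read_csv(src / "sites.csv")
    habitat = pd.read_csv(src / "habitat.csv")
    mast = pd.read_csv(src / "mast.csv")
    regional = pd.read_csv(src / "weather_regional.csv", index_col="date",
                           parse_dates=True)
    weather = {site: pd.read_csv(src / f"weather_{site}.csv", index_col="date",
                                 parse_dates=True)
               for site in sites["site"].unique()}
    veg_regional = pd.read_csv(src / "vegetation.csv", index_col="date",
                               parse_dates=True)
    veg_offsets = {idx: read_ascii_grid(src / f"veg_offset_{idx}.asc")[0]
                   for idx in ("ndvi", "evi", "ndwi")}
    native = read_ascii_grid(src / "landcover_source.asc")[0].astype(int)
    native12 = read_ascii_grid(src / "landcover_25m.asc")[0].astype(int)
    lc500 = read_ascii_grid(src / "landcover_500m.asc")[0].astype(int)
    lc1km = read_ascii_grid(src / "landcover_1km.asc")[0].astype(int)
    class_map = {int(k): int(v) for k, v in blob["class_map"].items()}

    return SyntheticWorld(
        config=config, sites=sites, weather=weather,
        weather_regional=regional, habitat=habitat, mast=mast,
        veg_regional=veg_regional, veg_offsets=veg_offsets,
        landcover_native=native, landcover_native12=native12,
        landcover_500m=lc500, landcover_1km=lc1km,
        class_map=class_map, truth=blob["truth"])


def write_observations(obs: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = obs[["site", "transect", "date", "aqt_count"]].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def read_observations(path: str | Path) -> pd.DataFrame:
    obs = pd.read_csv(path)
    obs["date"] = pd.to_datetime(obs["date"])
    return obs
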
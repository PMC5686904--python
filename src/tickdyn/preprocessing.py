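"""Dataset variants of the volunteer count signal.

Volunteer drag counts are zero-heavy (no ticks caught on a visit) and
occasionally peaky (a burst of activity on the sampling day). To measure
how much either pathology hampers learning, four variants of the
observation table are built: {zeros kept, zeros reduced} x {raw target,
Savitzky-Golay smoothed target}. Zero reduction removes every zero count
inside the tick season (March 1 - October 31) and a random half of the
zeros outside it; smoothing applies a least-squares polynomial filter per
transect, treating the monthly samples as equally spaced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

VARIANT_LABELS = ("kept_raw", "kept_smooth", "reduced_raw", "reduced_smooth")


@dataclass(frozen=True)
class VariantSpec:
    """Parameters of one dataset variant."""

    reduce_zeros: bool = False
    smooth: bool = False
    season_start: tuple[int, int] = (3, 1)     # (month, day), inclusive
    season_end: tuple[int, int] = (10, 31)
    out_season_removal_fraction: float = 0.5
    sg_window: int = 5
    sg_polyorder: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and exceed sg_polyorder")
        if not 0.0 <= self.out_season_removal_fraction <= 1.0:
            raise ValueError("out_season_removal_fraction must lie in [0, 1]")

    @property
    def label(self) -> str:
        return (("reduced" if self.reduce_zeros else "kept") + "_"
                + ("smooth" if self.smooth else "raw"))


@dataclass
class PreparedDataset:
    """An observation table with a modelling target column and its label."""

    frame: pd.DataFrame
    label: str


def in_season(dates: pd.Series, spec: VariantSpec = VariantSpec()) -> np.ndarray:
    """Boolean mask of dates inside the tick season (bounds inclusive)."""
    dates = pd.to_datetime(dates)
    md = dates.dt.month * 100 + dates.dt.day
    lo = spec.season_start[0] * 100 + spec.season_start[1]
    hi = spec.season_end[0] * 100 + spec.season_end[1]
    return ((md >= lo) & (md <= hi)).to_numpy()


def filter_zeros(obs: pd.DataFrame, spec: VariantSpec) -> pd.DataFrame:
    """Remove in-season zero counts and a seeded fraction of out-of-season ones.

    Non-zero rows are untouched and the original ordering is preserved; of
    the n out-of-season zeros, floor(fraction * n) are removed by a seeded
    uniform draw without replacement.
    """
    spec.validate()
    zero = obs["aqt_count"].to_numpy() == 0
    season = in_season(obs["date"], spec)
    drop = zero & season
    out_zero_idx = obs.index[zero & ~season]
    n_remove = int(np.floor(spec.out_season_removal_fraction
                            * len(out_zero_idx)))
    if n_remove:
        rng = np.random.default_rng(spec.seed)
        removed = rng.choice(out_zero_idx, size=n_remove, replace=False)
        drop |= obs.index.isin(removed)
    return obs.loc[~drop]


def smooth_series(counts, spec: VariantSpec = VariantSpec()) -> np.ndarray:
    """Savitzky-Golay smoothing of one transect's ordered count sequence.

    Observations are treated as equally spaced by sample index; edges are
    handled by the filter's polynomial fit over the terminal window and the
    result is floored at zero (negative tick counts are meaningless).
    Sequences shorter than the window are returned unchanged with a warning.
    """
    spec.validate()
    counts = np.asarray(counts, dtype=float)
    if counts.size < spec.sg_window:
        logger.warning("sequence of length %d shorter than window %d; "
                       "returned unsmoothed", counts.size, spec.sg_window)
        return counts
    smoothed = savgol_filter(counts, spec.sg_window, spec.sg_polyorder,
                             mode="interp")
    return np.maximum(smoothed, 0.0)


def prepare_dataset(obs: pd.DataFrame, spec: VariantSpec) -> PreparedDataset:
    """One variant: optional zero filtering, then an (optionally smoothed)
    ``target`` column; filtering precedes smoothing."""
    spec.validate()
    frame = filter_zeros(obs, spec) if spec.reduce_zeros else obs
    frame = frame.sort_values(["site", "transect", "date"]).reset_index(drop=True)
    if spec.smooth:
        target = np.empty(len(frame))
        for _, group in frame.groupby(["site", "transect"], sort=False):
            target[group.index.to_numpy()] = smooth_series(
                group["aqt_count"].to_numpy(), spec)
        frame = frame.assign(target=target)
    else:
        frame = frame.assign(target=frame["aqt_count"].astype(float))
    return PreparedDataset(frame=frame, label=spec.label)


def build_variants(obs: pd.DataFrame,
                   spec: VariantSpec = VariantSpec()) -> dict[str, PreparedDataset]:
    """The four labelled variants {kept, reduced} x {raw, smooth}."""
    out = {}
    for reduce_zeros in (False, True):
        for smooth in (False, True):
            variant = replace(spec, reduce_zeros=reduce_zeros, smooth=smooth)
            prepared = prepare_dataset(obs, variant)
            out[prepared.label] = prepared
    return out
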
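"""Time-aware random-forest regression of questing-tick counts.

A standard regression forest is not time-aware: trained on raw monthly
counts it mostly learns the seasonal cycle. Time-awareness is introduced by
a monthly Z-score transform of the target — counts are pooled per calendar
month across all sites and years, extreme values outside the inter-quartile
range are trimmed, and each count is standardized by its month's trimmed
mean and standard deviation. The forest then models departures from the
monthly norm, and error metrics are computed after mapping predictions back
to the count scale.

``TimeAwareForestRegressor`` packages the transform and the forest as a
scikit-learn estimator; the module-level functions expose the individual
steps (normalization fitting, z-scoring, repeated-run training and
evaluation) used by the experiment drivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

MONTH_COLUMN = "month"

#: per-transect goodness-of-fit bins
R2_BINS = (("moderate_to_strong", 0.7, 1.0), ("weak_to_moderate", 0.3, 0.7))


@dataclass(frozen=True)
class MonthlyNormalization:
    """Per-calendar-month trimmed moments defining the Z-score transform."""

    mu: np.ndarray      # shape (12,), month 1 at index 0
    sigma: np.ndarray
    q1: np.ndarray
    q3: np.ndarray

    def __post_init__(self):
        for name in ("mu", "sigma", "q1", "q3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have one entry per month")
            object.__setattr__(self, name, arr)
        if not np.all(self.sigma > 0):
            raise ValueError("sigma must be positive for every month")


def fit_monthly_normalization(values, months) -> MonthlyNormalization:
    """Trimmed mean/sd of the pooled values per calendar month.

    Per month, values strictly below the first or strictly above the third
    quartile (linear-interpolation quantiles) are discarded; the survivors'
    mean and sample standard deviation define the transform. A month with
    fewer than two survivors or zero variance gets sigma = 1.
    """
    values = np.asarray(values, dtype=float)
    months = np.asarray(months, dtype=int)
    mu = np.empty(12)
    sigma = np.empty(12)
    q1 = np.empty(12)
    q3 = np.empty(12)
    for m in range(1, 13):
        x = values[months == m]
        if x.size == 0:
            raise ValueError(f"no observations in calendar month {m}")
        lo, hi = np.quantile(x, [0.25, 0.75])  # linear interpolation
        survivors = x[(x >= lo) & (x <= hi)]
        q1[m - 1], q3[m - 1] = lo, hi
        if survivors.size == 0:
            # pathological spread (n=2): trimming removed everything
            warnings.warn(f"month {m}: no inter-quartile survivors, "
                          f"falling back to untrimmed values")
            survivors = x
        mu[m - 1] = survivors.mean()
        if survivors.size < 2 or survivors.std(ddof=1) == 0:
            warnings.warn(f"degenerate month {m}: sigma set to 1")
            sigma[m - 1] = 1.0
        else:
            sigma[m - 1] = survivors.std(ddof=1)
    return MonthlyNormalization(mu, sigma, q1, q3)


def zscore(values, months, norm: MonthlyNormalization) -> np.ndarray:
    """(value - mu_month) / sigma_month, applied to every observation."""
    values = np.asarray(values, dtype=float)
    months = np.asarray(months, dtype=int) - 1
    return (values - norm.mu[months]) / norm.sigma[months]


def inverse_zscore(z, months, norm: MonthlyNormalization,
                   clip: bool = False) -> np.ndarray:
    """z * sigma_month + mu_month; ``clip`` floors map products at zero."""
    z = np.asarray(z, dtype=float)
    months = np.asarray(months, dtype=int) - 1
    out = z * norm.sigma[months] + norm.mu[months]
    return np.maximum(out, 0.0) if clip else out


class TimeAwareForestRegressor(RegressorMixin, BaseEstimator):
    """Random-forest regression on monthly Z-scored targets.

    ``X`` must be a DataFrame containing ``month_col`` (calendar month
    1-12), which is used for the target transform and excluded from the
    predictors. ``predict`` returns de-normalized values on the count
    scale; set ``clip_predictions`` for map products floored at zero.
    """

    def __init__(self, n_estimators: int = 500, max_features: float = 1 / 3,
                 month_col: str = MONTH_COLUMN, clip_predictions: bool = False,
                 n_jobs: int | None = None, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.month_col = month_col
        self.clip_predictions = clip_predictions
        self.n_jobs = n_jobs
        self.random_state = random_state

    def _split_X(self, X: pd.DataFrame):
        if self.month_col not in X.columns:
            raise ValueError(f"X must contain a {self.month_col!r} column")
        months = X[self.month_col].to_numpy(dtype=int)
        return X.drop(columns=[self.month_col]), months

    def fit(self, X: pd.DataFrame, y, normalization: MonthlyNormalization
            | None = None):
        features, months = self._split_X(X)
        y = np.asarray(y, dtype=float)
        if features.isna().any().any() or np.isnan(y).any():
            raise ValueError("features and targets must be complete")
        self.normalization_ = normalization or fit_monthly_normalization(
            y, months)
        z = zscore(y, months, self.normalization_)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators, max_features=self.max_features,
            n_jobs=self.n_jobs, random_state=self.random_state)
        self.forest_.fit(features.to_numpy(dtype=float), z)
        self.feature_names_in_ = np.asarray(features.columns, dtype=object)
        imp = self.forest_.feature_importances_
        total = imp.sum()
        self.feature_importances_ = imp / total if total > 0 else imp
        return self

    def predict_z(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_")
        features, _ = self._split_X(X)
        features = features[list(self.feature_names_in_)]
        return self.forest_.predict(features.to_numpy(dtype=float))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        _, months = self._split_X(X)
        return inverse_zscore(self.predict_z(X), months, self.normalization_,
                              clip=self.clip_predictions)


@dataclass(frozen=True)
class ModelConfig:
    """Training protocol: one fixed 70/30 split, repeated seeded fits."""

    n_trees: int = 500
    features_per_split: float = 1 / 3
    train_fraction: float = 0.7
    n_runs: int = 10
    split_seed: int = 0
    run_seed: int = 1000
    n_jobs: int | None = None

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def run_seeds(self) -> list[int]:
        return [self.run_seed + i for i in range(self.n_runs)]


@dataclass
class ModelResult:
    """Per-run and averaged metrics of a repeated-run training."""

    feature_names: list[str]
    rmse_runs: list[float]
    nrmse_runs: list[float]
    importances_runs: list[np.ndarray]
    transect_r2: pd.DataFrame        # one row per run x transect
    predictions: pd.DataFrame        # test rows: truth/prediction per run
    normalization: MonthlyNormalization
    extras: dict = field(default_factory=dict)

    @property
    def rmse(self) -> float:
        return float(np.mean(self.rmse_runs))

    @property
    def nrmse(self) -> float:
        return float(np.mean(self.nrmse_runs))

    @property
    def importances(self) -> pd.Series:
        mean = np.mean(np.vstack(self.importances_runs), axis=0)
        return pd.Series(mean, index=self.feature_names)

    @property
    def mean_transect_r2(self) -> pd.Series:
        return self.transect_r2.groupby("transect")["r2"].mean()


def train_model(features: pd.DataFrame, z_targets, config: ModelConfig,
                run_seed: int) -> RandomForestRegressor:
    """One seeded forest fit on z-scored targets; importances normalized."""
    if features.isna().any().any():
        raise ValueError("feature matrix has missing values")
    forest = RandomForestRegressor(
        n_estimators=config.n_trees, max_features=config.features_per_split,
        n_jobs=config.n_jobs, random_state=run_seed)
    forest.fit(features.to_numpy(dtype=float), np.asarray(z_targets, float))
    return forest


def classify_r2(r2: float) -> str | None:
    for label, lo, hi in R2_BINS:
        if lo < r2 < hi:
            return label
    return None


def evaluate(pred_z, truth_z, months, transects,
             norm: MonthlyNormalization) -> dict:
    """De-normalized RMSE/NRMSE and per-transect goodness of fit.

    Metrics are computed on the unclipped count scale. NRMSE divides by the
    observed range of the de-normalized truth. Transects with fewer than 3
    test rows get an undefined (NaN) R².
    """
    months = np.asarray(months, dtype=int)
    pred = inverse_zscore(pred_z, months, norm)
    truth = inverse_zscore(truth_z, months, norm)
    err = pred - truth
    rmse = float(np.sqrt(np.mean(err ** 2)))
    truth_range = float(truth.max() - truth.min())
    nrmse = rmse / truth_range if truth_range > 0 else np.nan

    transects = np.asarray(transects, dtype=object)
    rows = []
    for t in pd.unique(transects):
        sel = transects == t
        if sel.sum() < 3:
            warnings.warn(f"transect {t}: fewer than 3 test rows, R2 undefined")
            r2 = np.nan
        else:
            r2 = float(r2_score(truth[sel], pred[sel]))
        rows.append({"transect": t, "r2": r2,
                     "fit_class": None if np.isnan(r2) else classify_r2(r2)})
    return {"rmse": rmse, "nrmse": nrmse, "pred": pred, "truth": truth,
            "transect_r2": pd.DataFrame(rows)}


def repeated_runs(table: pd.DataFrame, config: ModelConfig = ModelConfig(),
                  feature_columns: list[str] | None = None,
                  target_column: str = "target") -> ModelResult:
    """The full training protocol on a feature table.

    ``table`` carries key columns (site, transect, date), the target, and
    predictors. The monthly normalization is fitted on the pooled targets,
    a single seeded split reserves ``train_fraction`` for training, and
    ``n_runs`` forests differing only in their seed are fitted; metrics and
    importances are averaged across runs.
    """
    config.validate()
    table = table.reset_index(drop=True)
    dates = pd.to_datetime(table["date"])
    months = dates.dt.month.to_numpy()
    targets = table[target_column].to_numpy(dtype=float)
    if feature_columns is None:
        from .features import feature_names
        feature_columns = [c for c in feature_names() if c in table.columns]
    features = table[feature_columns]

    norm = fit_monthly_normalization(targets, months)
    z = zscore(targets, months, norm)

    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx, train_size=config.train_fraction, random_state=config.split_seed,
        shuffle=True)

    transects = (table["site"].astype(str) + "-" + table["transect"].astype(str)
                 ).to_numpy(dtype=object)

    rmse_runs, nrmse_runs, imp_runs, r2_frames = [], [], [], []
    pred_frame = table.loc[test_idx, ["site", "transect", "date",
                                      target_column]].copy()
    for run, seed in enumerate(config.run_seeds()):
        forest = train_model(features.iloc[train_idx], z[train_idx], config,
                             seed)
        pred_z = forest.predict(features.iloc[test_idx].to_numpy(dtype=float))
        res = evaluate(pred_z, z[test_idx], months[test_idx],
                       transects[test_idx], norm)
        rmse_runs.append(res["rmse"])
        nrmse_runs.append(res["nrmse"])
        imp = forest.feature_importances_
        total = imp.sum()
        imp_runs.append(imp / total if total > 0 else imp)
        frame = res["transect_r2"]
        frame.insert(0, "run", run)
        r2_frames.append(frame)
        pred_frame[f"pred_run{run}"] = res["pred"]
    pred_frame["truth_denorm"] = res["truth"]
    pred_frame["pred_mean"] = pred_frame[
        [f"pred_run{r}" for r in range(config.n_runs)]].mean(axis=1)

    return ModelResult(
        feature_names=list(feature_columns), rmse_runs=rmse_runs,
        nrmse_runs=nrmse_runs, importances_runs=imp_runs,
        transect_r2=pd.concat(r2_frames, ignore_index=True),
        predictions=pred_frame, normalization=norm,
        extras={"train_idx": train_idx, "test_idx": test_idx})
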
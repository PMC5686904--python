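"""The two computational experiments on the modelled tick counts.

1. Variant comparison: each of the four dataset variants is featurized and
   run through the repeated-run training protocol; the variant with the
   lowest (RMSE, NRMSE) — lexicographically — is selected.
2. Multi-scale importance: the selected dataset is modelled once per
   temporal scale, keeping the 24 non-weather features and adding the 7
   weather features of that scale (31 predictors per run, 11 runs), to see
   how driver importance shifts with the aggregation window. Importances
   are also reported for the full 101-feature model (top 10).

Displayed importances are multiplied by 100 and rounded (half-even) to
natural numbers, as in the source tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import (HABITAT_FEATURES, LANDCOVER_FEATURES, MAST_FEATURES,
                       VEGETATION_FEATURES, WEATHER_VARIABLES, WINDOWS,
                       assemble_features, feature_names)
from .model import ModelConfig, ModelResult, repeated_runs
from .preprocessing import PreparedDataset

NON_WEATHER_FEATURES = (tuple(HABITAT_FEATURES) + tuple(MAST_FEATURES)
                        + tuple(VEGETATION_FEATURES) + tuple(LANDCOVER_FEATURES))


def scale_feature_set(window: int) -> list[str]:
    """The 31 predictors of one temporal scale: 24 non-weather + 7 weather."""
    if window not in WINDOWS:
        raise ValueError(f"unknown temporal scale {window}")
    return list(NON_WEATHER_FEATURES) + [f"{v}-{window}"
                                         for v in WEATHER_VARIABLES]


def display_importance(importances: pd.Series) -> pd.Series:
    """x100, rounded half-even to integers (the tables' natural numbers)."""
    return pd.Series(np.round(importances.to_numpy() * 100).astype(int),
                     index=importances.index)


@dataclass
class VariantComparison:
    """Averaged metrics per dataset variant and the selected label."""

    metrics: pd.DataFrame                  # indexed by label: rmse, nrmse
    results: dict[str, ModelResult]
    selected: str

    def scatter_data(self, label: str) -> pd.DataFrame:
        """Prediction-vs-truth pairs (de-normalized) for one variant."""
        res = self.results[label]
        return res.predictions[["site", "transect", "date", "truth_denorm",
                                "pred_mean"]]


def compare_variants(variants: dict[str, PreparedDataset], world,
                     config: ModelConfig = ModelConfig()) -> VariantComparison:
    """Featurize and model the four variants; select by lowest (RMSE, NRMSE)."""
    results: dict[str, ModelResult] = {}
    rows = []
    for label, prepared in variants.items():
        table = assemble_features(prepared.frame, world)
        res = repeated_runs(table, config)
        results[label] = res
        rows.append({"label": label, "rmse": res.rmse, "nrmse": res.nrmse})
    metrics = pd.DataFrame(rows).set_index("label")
    selected = metrics.sort_values(["rmse", "nrmse"]).index[0]
    return VariantComparison(metrics=metrics, results=results,
                             selected=str(selected))


@dataclass
class ImportanceRanking:
    """Averaged importances per temporal scale plus the full-model top 10."""

    per_scale: dict[int, pd.Series]        # scale -> importances over 31 feats
    full_importances: pd.Series            # over the 101 features
    per_scale_results: dict[int, ModelResult]
    full_result: ModelResult

    def top(self, scale: int, n: int = 5) -> pd.DataFrame:
        imp = self.per_scale[scale].sort_values(ascending=False).head(n)
        return pd.DataFrame({"feature": imp.index,
                             "importance": imp.to_numpy(),
                             "display": display_importance(imp).to_numpy()})

    def full_top(self, n: int = 10) -> pd.DataFrame:
        imp = self.full_importances.sort_values(ascending=False).head(n)
        return pd.DataFrame({"feature": imp.index,
                             "importance": imp.to_numpy(),
                             "display": display_importance(imp).to_numpy()})

    def by_scale_table(self, n: int = 5) -> pd.DataFrame:
        rows = []
        for scale in self.per_scale:
            top = self.top(scale, n)
            for rank, rec in enumerate(top.itertuples(), start=1):
                rows.append({"scale_days": scale, "rank": rank,
                             "feature": rec.feature,
                             "importance": rec.importance,
                             "display": rec.display})
        return pd.DataFrame(rows)


def multiscale_importance(dataset: PreparedDataset, world,
                          config: ModelConfig = ModelConfig(),
                          scales: tuple[int, ...] = WINDOWS,
                          ) -> ImportanceRanking:
    """Importance rankings at each temporal scale and for the full model.

    All runs reuse the same seeded train/test split (the feature subset
    changes, the rows do not), keeping scales comparable.
    """
    table = assemble_features(dataset.frame, world)
    full_result = repeated_runs(table, config,
                                feature_columns=feature_names())
    per_scale: dict[int, pd.Series] = {}
    per_scale_results: dict[int, ModelResult] = {}
    for scale in scales:
        res = repeated_runs(table, config,
                            feature_columns=scale_feature_set(scale))
        per_scale[scale] = res.importances
        per_scale_results[scale] = res
    return ImportanceRanking(per_scale=per_scale,
                             full_importances=full_result.importances,
                             per_scale_results=per_scale_results,
                             full_result=full_result)
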
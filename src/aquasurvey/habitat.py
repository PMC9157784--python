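"""Forest-based regression of sample-unit richness on habitat variables.

A random-forest regressor predicts per-unit species richness from habitat
attributes (depth, fetch, littoral extent, shoreline composition and
proximity to introduction pathways).  Variable importance is the summed
Gini (impurity-decrease) contribution across all trees, expressed as a
percent of the total; the reduced model keeps variables holding >= 5% of
the total importance, minus shoreline-type variables that are impractical
to derive for new sites.  A depth-only baseline quantifies how much the
single dominant predictor explains on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split

from .design import RichnessSurface, SampleFrame

#: the habitat variables attributed to every sample unit
HABITAT_VARIABLES: tuple[str, ...] = (
    "mean_depth",
    "percent_littoral_zone",
    "maximum_fetch",
    "min_distance_soft_shore",
    "min_distance_hard_shore",
    "min_distance_moderate_shore",
    "min_distance_any_shore",
    "percent_soft_shore",
    "percent_hard_shore",
    "percent_moderate_shore",
    "min_distance_boat_launch",
    "min_distance_marina",
    "mid_distance_docked_shore",
    "min_distance_lots_of_docks",
    "proportion_shore_to_water",
    "percent_lots_of_docks",
    "percent_docks",
    "large_marina_presence",
)

#: reduced-model default: high-importance variables that are easy to derive
#: from commonly available GIS layers
REDUCED_VARIABLES: tuple[str, ...] = (
    "mean_depth",
    "percent_littoral_zone",
    "maximum_fetch",
    "min_distance_boat_launch",
    "min_distance_marina",
)

#: shoreline-type variables excluded from the reduced model (hard to derive
#: consistently for a novel site)
DEFAULT_EXCLUSIONS: tuple[str, ...] = (
    "min_distance_soft_shore",
    "percent_soft_shore",
)

IMPORTANCE_THRESHOLD_PERCENT = 5.0


@dataclass(frozen=True)
class ModelReport:
    r2_train: float
    r2_test: float
    r2_overall: float
    variables: tuple[str, ...]
    subset: str


@dataclass(frozen=True)
class FittedForest:
    model: RandomForestRegressor
    report: ModelReport

    @property
    def variables(self) -> tuple[str, ...]:
        return self.report.variables


def _subset_variables(
    habitat: pd.DataFrame,
    subset: Literal["all", "reduced", "depth_only"] | Sequence[str],
) -> list[str]:
    if subset == "all":
        cols = [v for v in HABITAT_VARIABLES if v in habitat.columns]
    elif subset == "reduced":
        cols = list(REDUCED_VARIABLES)
    elif subset == "depth_only":
        cols = ["mean_depth"]
    else:
        cols = list(subset)
    missing = [c for c in cols if c not in habitat.columns]
    if missing:
        raise ValueError(f"habitat table missing variable(s): {missing}")
    return cols


def fit_richness_forest(
    habitat: pd.DataFrame,
    richness: pd.Series | np.ndarray,
    subset: Literal["all", "reduced", "depth_only"] | Sequence[str] = "all",
    split_fraction: float = 0.8,
    seed: int = 0,
    n_estimators: int = 500,
) -> FittedForest:
    """Fit a seeded random-forest regression of richness on habitat variables.

    An 80/20 train/test split (seeded) yields train and test r²; the
    overall r² pools every unit.  Requires >= 20 units and non-constant
    richness.
    """
    cols = _subset_variables(habitat, subset)
    X = habitat[cols].to_numpy(float)
    y = np.asarray(richness, dtype=float)
    if len(y) != len(X):
        raise ValueError("richness length does not match habitat table")
    if len(y) < 20:
        raise ValueError("need at least 20 sample units to fit the forest")
    if np.ptp(y) == 0:
        raise ValueError("richness is constant; r-squared is undefined")
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, train_size=split_fraction, random_state=seed
    )
    model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    model.fit(Xtr, ytr)
    report = ModelReport(
        r2_train=float(r2_score(ytr, model.predict(Xtr))),
        r2_test=float(r2_score(yte, model.predict(Xte))),
        r2_overall=float(r2_score(y, model.predict(X))),
        variables=tuple(cols),
        subset=subset if isinstance(subset, str) else "custom",
    )
    return FittedForest(model=model, report=report)


def importance_percent(fitted: FittedForest) -> pd.DataFrame:
    """Summed Gini importance per variable and its percent of the total.

    The importance of a variable is the sum over all trees of the impurity
    decrease it produced; the percent column divides by the grand total.
    Sorted descending by importance.
    """
    sums = np.zeros(len(fitted.variables))
    for est in fitted.model.estimators_:
        sums += est.tree_.compute_feature_importances(normalize=False)
    table = pd.DataFrame(
        {"gini_sum": sums, "percent": 100.0 * sums / sums.sum()},
        index=pd.Index(fitted.variables, name="variable"),
    )
    return table.sort_values("gini_sum", ascending=False)


def reduced_variable_selection(
    importance: pd.DataFrame,
    threshold_percent: float = IMPORTANCE_THRESHOLD_PERCENT,
    exclude: Sequence[str] = DEFAULT_EXCLUSIONS,
) -> list[str]:
    """Variables holding at least ``threshold_percent`` of total importance.

    Exclusions are removed after thresholding.  Raises when nothing
    survives (suggesting a lower threshold).
    """
    if importance.empty:
        raise ValueError("importance table is empty")
    keep = importance.index[importance["percent"] >= threshold_percent]
    out = [v for v in keep if v not in set(exclude)]
    if not out:
        raise ValueError(
            f"no variables reach {threshold_percent}% importance after "
            "exclusions; lower the threshold"
        )
    return out


def predict_surface(fitted: FittedForest, frame: SampleFrame,
                    depth_mask_m: float | None = None) -> RichnessSurface:
    """Predict per-cell richness over a sample frame (clamped at 0).

    The frame must carry every model variable; the result feeds the
    percentile-surface weighting of the next survey's design.
    """
    missing = [v for v in fitted.variables if v not in frame.cells.columns]
    if missing:
        raise ValueError(f"frame missing model variable(s): {missing}")
    X = frame.cells[list(fitted.variables)].to_numpy(float)
    pred = np.clip(fitted.model.predict(X), 0.0, None)
    values = pd.Series(pred, index=frame.cells.index)
    if depth_mask_m is not None and "mean_depth" in frame.cells.columns:
        masked = frame.cells["mean_depth"] > depth_mask_m
    else:
        masked = pd.Series(False, index=frame.cells.index)
    return RichnessSurface(values=values, masked=masked)
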
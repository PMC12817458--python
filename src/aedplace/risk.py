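"""Risk-area binning, feature screening and the regression-tree risk model.

Alert counts per candidate isochrone are converted to average alerts per
year over the observation window, then binned into an ordinal risk area on
a 1..9 scale:

    level 1 : 0 alerts/year        level 6 : (4, 5]
    level 2 : (0, 1]               level 7 : (5, 10]
    level 3 : (1, 2]               level 8 : (10, 20]
    level 4 : (2, 3]               level 9 : > 20
    level 5 : (3, 4]

The risk area is regressed as a number on demographic/infrastructural
features with a decision tree so that risk can be estimated where no
historical alert locations exist; feature screening removes collinear
predictors (iterative VIF elimination) and keeps only features significant
in a one-way ANOVA F-test against the binned target.
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error
from sklearn.model_selection import KFold, train_test_split
from sklearn.tree import DecisionTreeRegressor
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .network import Point

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: right edges of the finite risk-area bins (levels 2..8); above the last
#: edge is level 9, an exact zero rate is level 1
_BIN_EDGES = (1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class ObservationWindow:
    """Date span over which alerts were recorded; years use 365.25 days."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("observation window end must be after start")

    @property
    def years(self) -> float:
        return (self.end - self.start).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class AlertRecord:
    """A dispatched suspected-OHCA alert with location and time."""

    id: int
    point: Point
    timestamp: datetime


def alerts_per_year(count: float, window: ObservationWindow) -> float:
    """Average alert rate over the observation window."""
    if count < 0:
        raise ValueError("alert count must be >= 0")
    return count / window.years


def bin_risk_area(rate: float) -> int:
    """Ordinal risk area 1..9 for an alerts-per-year rate.

    Intervals are half-open ``(a, b]``: a rate of exactly 1.0 is still
    level 2, while any strictly positive rate leaves level 1.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return 1
    return 2 + bisect.bisect_left(_BIN_EDGES, rate)


def screen_features(
    table: pd.DataFrame,
    features: Sequence[str] | None = None,
    target: str = "risk_area",
    vif_threshold: float = 10.0,
    alpha: float = 0.05,
) -> list[str]:
    """Collinearity removal followed by per-feature ANOVA significance.

    First, features are dropped one at a time — always the one with the
    highest variance inflation factor — until every remaining VIF is at or
    below ``vif_threshold`` (zero-variance features count as infinitely
    inflated). Then each survivor is tested with a one-way ANOVA F-test of
    its values grouped by the target's risk level; features with p >= alpha
    are discarded. Deterministic given column order.
    """
    if features is None:
        features = [c for c in table.columns if c != target]
    features = list(features)
    if len(features) < 2 or len(table) < 10:
        raise ValueError("need >= 2 features and >= 10 rows to screen")

    kept = list(features)
    while len(kept) > 1:
        x = table[kept].to_numpy(dtype=float)
        variances = x.var(axis=0)
        vifs = np.empty(len(kept))
        design = np.column_stack([x, np.ones(len(x))])
        for j in range(len(kept)):
            if variances[j] == 0:
                vifs[j] = np.inf
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                vifs[j] = variance_inflation_factor(design, j)
        vifs = np.where(np.isnan(vifs), np.inf, vifs)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_threshold:
            break
        logger.debug("dropping collinear feature %s (VIF=%.2f)", kept[worst], vifs[worst])
        kept.pop(worst)

    y = table[target].to_numpy()
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("target has a single level; F-test undefined")
    retained = []
    for name in kept:
        col = table[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            continue  # constant feature carries no signal
        groups = [col[y == lv] for lv in levels]
        _, p = stats.f_oneway(*groups)
        if np.isnan(p):
            continue
        if p < alpha:
            retained.append(name)
    if not retained:
        raise ValueError("all features eliminated during screening")
    return retained


@dataclass
class RiskModel:
    """A fitted regression tree predicting the 1..9 risk area, with metrics."""

    estimator: DecisionTreeRegressor
    selected_features: list[str]
    cv_mse: float
    cv_mae: float
    test_mse: float
    test_mae: float
    max_depth: int
    min_samples_leaf: int
    seed: int
    linear_test_mse: float | None = None
    linear_test_mae: float | None = None
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    def predict_score(self, features: dict[str, float] | pd.DataFrame) -> np.ndarray:
        """Un-rounded tree output; raises ``KeyError`` naming a missing feature."""
        if isinstance(features, dict):
            features = pd.DataFrame([features])
        for name in self.selected_features:
            if name not in features.columns:
                raise KeyError(f"missing feature {name!r}")
        x = features[self.selected_features].to_numpy(dtype=float)
        return self.estimator.predict(x)

    def to_dict(self) -> dict:
        """JSON-ready summary: tree structure, metrics, selected features."""
        t = self.estimator.tree_

        def node(i: int) -> dict:
            if t.children_left[i] == -1:
                return {"leaf_value": float(t.value[i][0][0]), "n": int(t.n_node_samples[i])}
            return {
                "feature": self.selected_features[t.feature[i]],
                "threshold": float(t.threshold[i]),
                "left": node(int(t.children_left[i])),
                "right": node(int(t.children_right[i])),
            }

        return {
            "selected_features": self.selected_features,
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "cv_mse": self.cv_mse,
            "cv_mae": self.cv_mae,
            "test_mse": self.test_mse,
            "test_mae": self.test_mae,
            "linear_test_mse": self.linear_test_mse,
            "linear_test_mae": self.linear_test_mae,
            "tree": node(0),
        }


def fit_risk_tree(
    table: pd.DataFrame,
    features: Sequence[str],
    target: str = "risk_area",
    split_fraction: float = 0.8,
    folds: int = 5,
    seed: int = 0,
    depth_grid: Sequence[int] = (2, 3, 4, 5, 6),
    min_leaf_grid: Sequence[int] = (5, 10, 20),
) -> RiskModel:
    """Fit the regression tree with an 80/20 split and 5-fold CV model choice.

    Tree depth and minimum leaf size are chosen over a small grid by minimum
    cross-validated MSE on the training split; ties go to the shallower tree
    and, within a depth, to the larger (more regularised) leaf size. A
    linear-regression baseline is fitted on the same split for comparison
    only. Fully reproducible given ``seed``.
    """
    if len(table) < 25:
        raise ValueError("need >= 25 rows to fit the risk tree")
    features = list(features)
    x = table[features].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)

    x_train, x_test, y_train, y_test = train_test_split(
        x, y, train_size=split_fraction, random_state=seed, shuffle=True
    )

    if np.ptp(y_train) == 0:
        logger.warning("constant training target; fitting a single-leaf model")
        grid = [(1, 1)]
    else:
        grid = [(d, m) for d in sorted(depth_grid) for m in sorted(min_leaf_grid, reverse=True)]

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    records = []
    for depth, min_leaf in grid:
        mses, maes = [], []
        for tr, va in kf.split(x_train):
            est = DecisionTreeRegressor(
                max_depth=depth, min_samples_leaf=min_leaf, random_state=seed
            )
            est.fit(x_train[tr], y_train[tr])
            pred = est.predict(x_train[va])
            mses.append(mean_squared_error(y_train[va], pred))
            maes.append(mean_absolute_error(y_train[va], pred))
        records.append(
            {"max_depth": depth, "min_samples_leaf": min_leaf,
             "cv_mse": float(np.mean(mses)), "cv_mae": float(np.mean(maes))}
        )
    cv_table = pd.DataFrame(records)
    best = int(np.argmin(cv_table["cv_mse"].to_numpy()))  # first minimum = simplest
    depth = int(cv_table.loc[best, "max_depth"])
    min_leaf = int(cv_table.loc[best, "min_samples_leaf"])

    est = DecisionTreeRegressor(max_depth=depth, min_samples_leaf=min_leaf, random_state=seed)
    est.fit(x_train, y_train)
    pred_test = est.predict(x_test)

    lin = LinearRegression().fit(x_train, y_train)
    lin_pred = lin.predict(x_test)

    return RiskModel(
        estimator=est,
        selected_features=features,
        cv_mse=float(cv_table.loc[best, "cv_mse"]),
        cv_mae=float(cv_table.loc[best, "cv_mae"]),
        test_mse=float(mean_squared_error(y_test, pred_test)),
        test_mae=float(mean_absolute_error(y_test, pred_test)),
        max_depth=depth,
        min_samples_leaf=min_leaf,
        seed=seed,
        linear_test_mse=float(mean_squared_error(y_test, lin_pred)),
        linear_test_mae=float(mean_absolute_error(y_test, lin_pred)),
        cv_table=cv_table,
    )


def predict_risk(model: RiskModel, features: dict[str, float]) -> int:
    """Tree output rounded to the nearest integer and clamped to [1, 9]."""
    score = float(model.predict_score(features)[0])
    return int(min(9, max(1, round(score))))
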
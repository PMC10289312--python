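"""Random-Forest estimation of execution-score deductions.

Covers the day-wise sequential train/test split (the last recording days are
held out to avoid day-level leakage), forest training with mean-squared-error
splits, impurity-based feature importances with threshold selection,
root-to-leaf decision-rule extraction, and the single-feature baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor

from .errors import InputError, SplitError
from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "PerformanceRecord",
    "ForestParams",
    "DeductionModel",
    "Metrics",
    "RulePath",
    "records_to_frame",
    "frame_to_records",
    "sequential_split",
    "train_forest",
    "evaluate",
    "select_features",
    "extract_rules",
    "fit_single_feature_baseline",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class PerformanceRecord:
    """Features plus scoring context for one performance."""

    gymnast_id: str
    day: int
    features: FeatureVector
    judge_deductions: tuple[float, float]

    def __post_init__(self) -> None:
        for d in self.judge_deductions:
            if not 0.0 <= d <= 6.0:
                raise InputError(f"judge deduction {d} outside [0, 6]")

    @property
    def mean_deduction(self) -> float:
        return float(np.mean(self.judge_deductions))


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters (library defaults; the split criterion is MSE)."""

    n_estimators: int = 100
    max_depth: int | None = None
    max_features: float | int | str | None = 1.0
    min_samples_leaf: int = 1


@dataclass(frozen=True)
class Metrics:
    rmse: float
    r2: float
    r2_defined: bool = True

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "r2": self.r2, "r2_defined": self.r2_defined}


@dataclass
class DeductionModel:
    """A fitted forest plus its importances and split bookkeeping."""

    forest: RandomForestRegressor
    feature_names: tuple[str, ...]
    importances: dict[str, float]
    train_days: tuple[int, ...] = ()
    test_days: tuple[int, ...] = ()
    seed: int = 0
    degenerate: bool = False  # constant training target; importances are void

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict(np.asarray(X, dtype=float))


@dataclass(frozen=True)
class RulePath:
    """One root-to-leaf decision path of a regression tree."""

    conditions: tuple[tuple[str, str, float], ...]  # (feature, "<=" or ">", thr)
    leaf_prediction: float
    n_samples: int

    def as_dict(self) -> dict:
        return {
            "conditions": [list(c) for c in self.conditions],
            "leaf_prediction": self.leaf_prediction,
            "n_samples": self.n_samples,
        }


# ---------------------------------------------------------------------------
# Record <-> table conversion
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[PerformanceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"gymnast": r.gymnast_id, "day": r.day}
        row.update(r.features.as_dict())
        row["judge1"], row["judge2"] = r.judge_deductions
        row["mean_deduction"] = r.mean_deduction
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[PerformanceRecord]:
    records = []
    for _, row in frame.iterrows():
        fv = FeatureVector(values=tuple(float(row[n]) for n in FEATURE_NAMES))
        records.append(
            PerformanceRecord(
                gymnast_id=str(row["gymnast"]),
                day=int(row["day"]),
                features=fv,
                judge_deductions=(float(row["judge1"]), float(row["judge2"])),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Split / train / evaluate
# ---------------------------------------------------------------------------

def sequential_split(
    records: Sequence[PerformanceRecord], n_test_days: int = 2
) -> tuple[list[PerformanceRecord], list[PerformanceRecord]]:
    """Hold out every record from the ``n_test_days`` latest days.

    Day-wise holdout prevents within-day leakage between train and test.
    Raises :class:`SplitError` when there are not strictly more distinct
    days than ``n_test_days`` (the training set may not be empty).
    """
    if n_test_days < 1:
        raise SplitError(f"n_test_days must be >= 1, got {n_test_days}")
    days = sorted({r.day for r in records})
    if len(days) <= n_test_days:
        raise SplitError(
            f"need more than {n_test_days} distinct days, got {len(days)}"
        )
    test_days = set(days[-n_test_days:])
    train = [r for r in records if r.day not in test_days]
    test = [r for r in records if r.day in test_days]
    return train, test


def _design(records: Sequence[PerformanceRecord]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([r.features.as_array() for r in records], dtype=float)
    y = np.array([r.mean_deduction for r in records], dtype=float)
    return X, y


def train_forest(
    train: Sequence[PerformanceRecord],
    params: ForestParams = ForestParams(),
    seed: int = 0,
) -> DeductionModel:
    """Fit a regression forest (MSE split criterion) on the training records.

    Feature importances are the forest's mean decrease in impurity,
    normalized to sum to one.  A constant target still trains but flags the
    model degenerate, since the importances carry no information.
    """
    if len(train) < 2:
        raise InputError(f"need >= 2 training records, got {len(train)}")
    X, y = _design(train)
    forest = RandomForestRegressor(
        n_estimators=params.n_estimators,
        criterion="squared_error",
        max_depth=params.max_depth,
        max_features=params.max_features,
        min_samples_leaf=params.min_samples_leaf,
        random_state=seed,
    )
    forest.fit(X, y)
    degenerate = bool(np.ptp(y) == 0.0)
    importances = dict(zip(FEATURE_NAMES, map(float, forest.feature_importances_)))
    return DeductionModel(
        forest=forest,
        feature_names=tuple(FEATURE_NAMES),
        importances=importances,
        seed=seed,
        degenerate=degenerate,
    )


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return Metrics(rmse=rmse, r2=float("nan"), r2_defined=False)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return Metrics(rmse=rmse, r2=r2)


def evaluate(model: DeductionModel, test: Sequence[PerformanceRecord]) -> Metrics:
    """RMSE and coefficient of determination on a held-out set."""
    if len(test) == 0:
        raise InputError("test set is empty")
    X, y = _design(test)
    return _metrics(y, model.predict(X))


def select_features(model: DeductionModel, threshold: float = 0.1) -> list[str]:
    """Features with importance >= threshold, sorted descending by importance."""
    if not 0.0 <= threshold <= 1.0:
        raise InputError(f"threshold must be in [0, 1], got {threshold}")
    chosen = [
        (name, imp)
        for name, imp in model.importances.items()
        if imp >= threshold and imp > 0.0
    ]
    chosen.sort(key=lambda item: (-item[1], item[0]))
    return [name for name, _ in chosen]


# ---------------------------------------------------------------------------
# Rule extraction
# ---------------------------------------------------------------------------

def extract_rules(
    tree: DecisionTreeRegressor, feature_names: Sequence[str] = FEATURE_NAMES
) -> list[RulePath]:
    """Enumerate every root-to-leaf path of a fitted regression tree.

    Paths come out in depth-first order with the left ("<=") branch first,
    matching the binary-tree comparator convention: left means
    feature <= threshold, right means feature > threshold.
    """
    t = tree.tree_
    paths: list[RulePath] = []

    def walk(node: int, conditions: list[tuple[str, str, float]]) -> None:
        if t.children_left[node] == -1:  # leaf
            paths.append(
                RulePath(
                    conditions=tuple(conditions),
                    leaf_prediction=float(t.value[node].ravel()[0]),
                    n_samples=int(t.n_node_samples[node]),
                )
            )
            return
        name = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conditions + [(name, "<=", thr)])
        walk(t.children_right[node], conditions + [(name, ">", thr)])

    walk(0, [])
    return paths


# ---------------------------------------------------------------------------
# Single-feature baseline
# ---------------------------------------------------------------------------

def fit_single_feature_baseline(
    records: Sequence[PerformanceRecord],
    feature: str,
    split: tuple[Sequence[PerformanceRecord], Sequence[PerformanceRecord]],
    regressor: str = "ols",
    seed: int = 0,
) -> Metrics:
    """Test metrics of a one-feature reference model (OLS by default).

    ``regressor`` may be ``"ols"`` or ``"forest"``.  A constant training
    feature is a degenerate fit and raises :class:`InputError`.
    """
    if feature not in FEATURE_NAMES:
        raise InputError(f"unknown feature {feature!r}")
    idx = FEATURE_NAMES.index(feature)
    train, test = split
    Xtr, ytr = _design(train)
    Xte, yte = _design(test)
    xtr = Xtr[:, [idx]]
    xte = Xte[:, [idx]]
    if np.ptp(xtr) == 0.0:
        raise InputError(f"feature {feature!r} is constant on the training set")
    if regressor == "ols":
        est = LinearRegression()
    elif regressor == "forest":
        est = RandomForestRegressor(
            n_estimators=100, criterion="squared_error", random_state=seed
        )
    else:
        raise InputError(f"unknown regressor {regressor!r}")
    est.fit(xtr, ytr)
    return _metrics(yte, est.predict(xte))


# ---------------------------------------------------------------------------
# Persistence: versioned binary + JSON sidecar
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(model: DeductionModel, path: str | Path, metrics: Metrics | None = None,
               rules: Iterable[RulePath] = ()) -> None:
    path = Path(path)
    joblib.dump({"version": _MODEL_FORMAT_VERSION, "model": model}, path)
    sidecar = {
        "version": _MODEL_FORMAT_VERSION,
        "feature_names": list(model.feature_names),
        "importances": model.importances,
        "train_days": list(model.train_days),
        "test_days": list(model.test_days),
        "seed": model.seed,
        "degenerate": model.degenerate,
        "metrics": metrics.as_dict() if metrics is not None else None,
        "rules": [r.as_dict() for r in rules],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> DeductionModel:
    payload = joblib.load(path)
    if payload.get("version") != _MODEL_FORMAT_VERSION:
        raise InputError(f"unsupported model format version {payload.get('version')}")
    return payload["model"]
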
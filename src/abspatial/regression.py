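"""Descriptor-based aggregation-rate modelling.

Implements the small-data workflow used to relate the 30 spatial descriptors
to experimental aggregation rates: exhaustive enumeration of all size-k
feature subsets scored by mean squared error under repeated k-fold
cross-validation, model fitting and hyperparameter tuning for four families
(linear, k-nearest-neighbour, support-vector and random-forest regression)
within fixed grids, leave-one-out cross-validation, and the reliability rule
that accepts a model only if its correlation coefficient drops by at most
0.3 from fit to LOOCV.

Feature standardisation is applied inside every fold for the KNN and SVR
families (distance/kernel based); tree and linear fits run on raw features.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import LeaveOneOut, RepeatedKFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.base import clone

from .structure import canonical_descriptor_names

DEFAULT_TARGET = "Aggregation_Rate"
FAMILIES = ("linear", "knn", "svr", "rf")

# Tuning-grid bounds; out-of-range values are rejected.
GRID_BOUNDS = {
    "knn": {"n_neighbors": (2, 8)},
    "svr": {"C": (5.0, 15.0), "epsilon": (0.1, 0.5)},
    "rf": {"max_depth": (2, 6)},
}
DEFAULT_GRIDS = {
    "linear": {},
    "knn": {"n_neighbors": list(range(2, 9))},
    "svr": {"C": [5.0, 7.5, 10.0, 12.5, 15.0],
            "epsilon": [0.1, 0.2, 0.3, 0.4, 0.5]},
    "rf": {"max_depth": [2, 3, 4, 5, 6]},
}
STANDARDIZED_FAMILIES = ("knn", "svr")


@dataclass(frozen=True)
class FeatureTable:
    """Antibodies x descriptors with one experimental target column."""

    frame: pd.DataFrame
    target: str = DEFAULT_TARGET

    def __post_init__(self) -> None:
        if self.target not in self.frame.columns:
            raise ValueError(f"missing target column {self.target!r}")
        if self.frame.isna().any().any():
            raise ValueError("feature table must not contain missing values")
        vocab = set(canonical_descriptor_names())
        unknown = [c for c in self.feature_names if c not in vocab]
        if unknown:
            raise ValueError(f"unknown descriptor columns: {unknown}")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.target]

    def X(self, subset: tuple[str, ...] | None = None) -> np.ndarray:
        cols = list(subset) if subset is not None else self.feature_names
        return self.frame[cols].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.target].to_numpy(dtype=float)


@dataclass(frozen=True)
class SubsetResult:
    features: tuple[str, ...]
    mse: float
    family: str
    params: dict


@dataclass(frozen=True)
class LoocvResult:
    predictions: np.ndarray  # one held-out prediction per row
    r: float                 # NaN when the target is constant
    mse: float


def validate_params(family: str, params: dict) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    for key, value in params.items():
        bounds = GRID_BOUNDS.get(family, {}).get(key)
        if bounds is not None:
            lo, hi = bounds
            vals = np.atleast_1d(value)
            if np.any(vals < lo) or np.any(vals > hi):
                raise ValueError(
                    f"{family} parameter {key}={value} outside [{lo}, {hi}]"
                )


def make_estimator(family: str, params: dict | None = None,
                   standardize: bool | None = None, seed: int = 0):
    params = dict(params or {})
    validate_params(family, params)
    if family == "linear":
        est = LinearRegression(**params)
    elif family == "knn":
        est = KNeighborsRegressor(**params)
    elif family == "svr":
        est = SVR(**params)
    else:
        est = RandomForestRegressor(random_state=seed, **params)
    if standardize is None:
        standardize = family in STANDARDIZED_FAMILIES
    return make_pipeline(StandardScaler(), est) if standardize else est


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# Exhaustive feature selection
# ---------------------------------------------------------------------------

def _linear_cv_mse(X: np.ndarray, y: np.ndarray, splits) -> float:
    """Fast ordinary-least-squares CV for the exhaustive search hot loop."""
    errs = []
    for tr, te in splits:
        A = np.column_stack([np.ones(len(tr)), X[tr]])
        coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        pred = np.column_stack([np.ones(len(te)), X[te]]) @ coef
        errs.append(np.mean((pred - y[te]) ** 2))
    return float(np.mean(errs))


def exhaustive_select(
    table: FeatureTable,
    k: int,
    family: str = "linear",
    params: dict | None = None,
    folds: int = 4,
    repeats: int = 5,
    seed: int = 0,
    top: int | None = None,
) -> list[SubsetResult]:
    """Score every size-k feature subset by repeated k-fold mean MSE.

    Results are ranked ascending by MSE, ties broken lexicographically on the
    sorted feature names, so a fixed seed gives a fixed ranking.
    """
    features = table.feature_names
    if k > len(features):
        raise ValueError(f"k={k} exceeds the {len(features)} available features")
    if len(table.frame) < folds:
        raise ValueError("fewer rows than CV folds")
    params = dict(params or {})
    validate_params(family, params)

    y = table.y
    Xall = table.X()
    col = {name: i for i, name in enumerate(features)}
    cv = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = [(tr, te) for tr, te in cv.split(Xall)]

    results = []
    if family == "linear" and not params:
        for subset in combinations(features, k):
            X = Xall[:, [col[f] for f in subset]]
            results.append(SubsetResult(subset, _linear_cv_mse(X, y, splits),
                                        family, params))
    else:
        base = make_estimator(family, params, seed=seed)
        for subset in combinations(features, k):
            X = Xall[:, [col[f] for f in subset]]
            errs = []
            for tr, te in splits:
                est = clone(base)
                est.fit(X[tr], y[tr])
                errs.append(np.mean((est.predict(X[te]) - y[te]) ** 2))
            results.append(SubsetResult(subset, float(np.mean(errs)),
                                        family, params))
    results.sort(key=lambda r: (r.mse, tuple(sorted(r.features))))
    return results[:top] if top else results


# ---------------------------------------------------------------------------
# Fitting, LOOCV, tuning
# ---------------------------------------------------------------------------

def loocv(
    table: FeatureTable,
    subset: tuple[str, ...],
    family: str = "linear",
    params: dict | None = None,
    seed: int = 0,
) -> LoocvResult:
    """Leave-one-out predictions: each row predicted by a fit on the rest."""
    if len(table.frame) < 3:
        raise ValueError("LOOCV needs at least 3 rows")
    X, y = table.X(subset), table.y
    preds = np.empty(len(y))
    base = make_estimator(family, params, seed=seed)
    for tr, te in LeaveOneOut().split(X):
        est = clone(base)
        est.fit(X[tr], y[tr])
        preds[te] = est.predict(X[te])
    return LoocvResult(predictions=preds, r=_pearson(y, preds),
                       mse=float(np.mean((preds - y) ** 2)))


def fit_and_tune(
    table: FeatureTable,
    subset: tuple[str, ...],
    family: str = "linear",
    grid: dict | None = None,
    criterion: str = "loocv",
    folds: int = 4,
    repeats: int = 5,
    seed: int = 0,
) -> dict:
    """Grid-search a family on one feature subset.

    Hyperparameters are selected by LOOCV MSE by default (``criterion`` can
    be ``"kfold"``). Returns the best parameters, the refit estimator, the
    in-sample (fit) r and MSE, and the LOOCV result under the best
    parameters. A constant target makes r undefined (NaN); MSE is still
    reported.
    """
    grid = {k: list(v) for k, v in (grid or DEFAULT_GRIDS[family]).items()}
    validate_params(family, grid)
    if criterion not in ("loocv", "kfold"):
        raise ValueError("criterion must be 'loocv' or 'kfold'")
    X, y = table.X(subset), table.y

    def cv_mse(params: dict) -> float:
        if criterion == "loocv":
            return loocv(table, subset, family, params, seed=seed).mse
        cv = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
        errs = []
        for tr, te in cv.split(X):
            est = make_estimator(family, params, seed=seed)
            est.fit(X[tr], y[tr])
            errs.append(np.mean((est.predict(X[te]) - y[te]) ** 2))
        return float(np.mean(errs))

    keys = sorted(grid)
    candidates = [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))] or [{}]
    scored = [(cv_mse(params), i, params) for i, params in enumerate(candidates)]
    scored.sort(key=lambda t: (t[0], t[1]))
    best_params = scored[0][2]

    est = make_estimator(family, best_params, seed=seed)
    est.fit(X, y)
    fitted = est.predict(X)
    return {
        "family": family,
        "subset": tuple(subset),
        "best_params": best_params,
        "estimator": est,
        "fit_r": _pearson(y, fitted),
        "fit_mse": float(np.mean((fitted - y) ** 2)),
        "loocv": loocv(table, subset, family, best_params, seed=seed),
    }


def reliability_check(fit_r: float, loocv_r: float, max_drop: float = 0.3) -> bool:
    """Accept iff the correlation drop from fit to LOOCV is at most 0.3."""
    if np.isnan(fit_r) or np.isnan(loocv_r):
        raise ValueError("reliability check needs defined correlation values")
    return bool(fit_r - loocv_r <= max_drop + 1e-12)  # inclusive boundary
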
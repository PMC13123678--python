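"""Procedure-duration prediction.

The pipeline follows the usual tabular-regression recipe: clean the raw
waiting list (drop rows with missing or implausible duration labels),
one-hot encode the categorical features, select features by wrapper
backward elimination scored with cross-validated MAE, fit one of a small
family of regressors, and convert a predicted procedure time into a planned
appointment length by adding a fixed 15-minute buffer (or ignoring the
prediction entirely in fixed-30-minute baseline mode).

Backward elimination works at the level of *feature groups*: dropping a
categorical feature removes all of its one-hot columns at once, with a
group's importance taken as the sum of the fitted model's per-column
importances (permutation importance as a fallback for models that expose
none).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

from .domain import (AGE_BANDS, BMI_BANDS, BUFFER_MINUTES, DURATION_BOUNDS,
                     ENDOSCOPIST_TYPES, FAILED_REASONS, FIXED_SLOT_MINUTES,
                     INDICATIONS, PRIORITIES, PROCEDURE_TYPES, SEXES,
                     CapabilityError, ConfigurationError,
                     InvalidPredictionError, NoUsableDataError, Patient)

__all__ = [
    "FEATURE_GROUPS",
    "FeatureMatrix",
    "SelectionTrace",
    "cohort_frame",
    "clean",
    "split_frame",
    "backward_eliminate",
    "fit_predict",
    "make_regressor",
    "appointment_duration",
    "DurationModel",
    "REGRESSOR_NAMES",
]

# Feature schema in waiting-list order; value None marks a numeric column.
_CATEGORIES = {
    "sex": SEXES,
    "age_band": AGE_BANDS,
    "bmi_band": BMI_BANDS,
    "priority": PRIORITIES,
    "comorbidity_score": None,
    "respiratory": None,
    "cardiovascular": None,
    "diabetes": None,
    "prior_pelvic_surgery": None,
    "past_failed_colonoscopy": None,
    "failed_reason": FAILED_REASONS,
    "procedure_type": PROCEDURE_TYPES,
    "indication": INDICATIONS,
    "endoscopist_type": ENDOSCOPIST_TYPES,
}
FEATURE_GROUPS = tuple(_CATEGORIES)
LABEL = "actual_procedure_minutes"

REGRESSOR_NAMES = ("linear", "random_forest", "gradient_boosted_trees",
                   "gaussian_process", "multilayer_perceptron")


def make_regressor(name: str, seed: int = 0):
    """A fresh estimator of the named family with fixed, sane defaults."""
    if name == "linear":
        return LinearRegression()
    if name == "random_forest":
        return RandomForestRegressor(n_estimators=200, random_state=seed,
                                     n_jobs=1)
    if name == "gradient_boosted_trees":
        # Conservative small-data settings: a minimum loss reduction per
        # split (gamma) and a minimum leaf weight keep pure-noise splits out
        # of the trees, which gain-based feature ranking relies on.
        return XGBRegressor(n_estimators=150, max_depth=4, learning_rate=0.1,
                            gamma=1.0, min_child_weight=10,
                            tree_method="hist",
                            random_state=seed, n_jobs=1, verbosity=0)
    if name == "gaussian_process":
        return GaussianProcessRegressor(alpha=1.0, random_state=seed,
                                        normalize_y=True)
    if name == "multilayer_perceptron":
        return MLPRegressor(hidden_layer_sizes=(32, 16), max_iter=500,
                            random_state=seed)
    raise ConfigurationError(f"unknown regressor spec {name!r}; "
                             f"choose one of {REGRESSOR_NAMES}")


@dataclass
class FeatureMatrix:
    """Encoded design matrix with its label and the group -> columns map."""

    X: pd.DataFrame
    y: pd.Series
    groups: dict

    def restrict(self, group_names: Sequence[str]) -> "FeatureMatrix":
        cols = [c for g in group_names for c in self.groups[g]]
        return FeatureMatrix(self.X[cols], self.y,
                             {g: self.groups[g] for g in group_names})

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class SelectionTrace:
    """History of one backward-elimination run.

    ``steps`` records, per iteration, the feature removed *after* that
    iteration's candidate set was scored, together with the set's
    cross-validated MAE. ``evaluated`` holds every (feature set, MAE) pair
    scored along the way; ``selected_features`` is the best-scoring set
    whose size does not exceed the cap.
    """

    steps: list = field(default_factory=list)
    evaluated: list = field(default_factory=list)
    selected_features: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"n_features": len(fs), "features": "|".join(fs), "cv_mae": mae}
             for fs, mae in self.evaluated])


def cohort_frame(cohort: Sequence[Patient]) -> pd.DataFrame:
    """Raw (unencoded) feature table of a cohort, label included."""
    rows = []
    for p in cohort:
        rows.append({
            "id": p.id, "sex": p.sex, "age_band": p.age_band,
            "bmi_band": p.bmi_band, "priority": p.priority,
            "comorbidity_score": p.comorbidity_score,
            "respiratory": p.respiratory, "cardiovascular": p.cardiovascular,
            "diabetes": p.diabetes,
            "prior_pelvic_surgery": p.prior_pelvic_surgery,
            "past_failed_colonoscopy": p.past_failed_colonoscopy,
            "failed_reason": p.failed_reason,
            "procedure_type": p.procedure_type, "indication": p.indication,
            "endoscopist_type": p.endoscopist_type,
            LABEL: p.actual_procedure_minutes,
        })
    return pd.DataFrame(rows)


def _encode(raw: pd.DataFrame) -> FeatureMatrix:
    cols = {}
    groups = {}
    for name, cats in _CATEGORIES.items():
        if cats is None:
            cols[name] = raw[name].astype(float)
            groups[name] = [name]
        else:
            groups[name] = []
            for cat in cats:
                col = f"{name}={cat}"
                cols[col] = (raw[name] == cat).astype(float)
                groups[name].append(col)
    X = pd.DataFrame(cols, index=raw.index)
    y = raw[LABEL].astype(float)
    return FeatureMatrix(X, y, groups)


def clean(raw) -> FeatureMatrix:
    """Drop rows with missing, nonpositive or implausible duration labels
    and encode the rest. Accepts a raw feature table or a cohort of
    patients. Raises if nothing survives."""
    if not isinstance(raw, pd.DataFrame):
        raw = cohort_frame(raw)
    lo, hi = DURATION_BOUNDS
    label = pd.to_numeric(raw[LABEL], errors="coerce")
    keep = label.notna() & (label > 0) & (label >= lo) & (label <= hi)
    kept = raw.loc[keep].reset_index(drop=True)
    if kept.empty:
        raise NoUsableDataError("no rows with a usable duration label")
    return _encode(kept)


def split_frame(fm: FeatureMatrix, test_fraction: float = 0.2,
                seed: int = 0) -> tuple:
    """Random train/test split of an encoded matrix (default 80/20)."""
    rng = np.random.default_rng(seed)
    n = len(fm)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    return (FeatureMatrix(fm.X.iloc[train_idx], fm.y.iloc[train_idx], fm.groups),
            FeatureMatrix(fm.X.iloc[test_idx], fm.y.iloc[test_idx], fm.groups))


def _group_importances(model, fm: FeatureMatrix, seed: int) -> dict:
    # Group importance must be additive over a group's one-hot columns, so
    # use *total* loss reduction per column where available (XGBoost's
    # total_gain); per-split averages would bias toward wide groups.
    booster = getattr(model, "get_booster", None)
    if booster is not None:
        score = booster().get_score(importance_type="total_gain")
        imp = np.array([score.get(f"f{j}", 0.0)
                        for j in range(fm.X.shape[1])])
    else:
        imp = getattr(model, "feature_importances_", None)
    if imp is None:
        coef = getattr(model, "coef_", None)
        if coef is not None:
            imp = np.abs(np.ravel(coef))
        else:
            try:
                imp = permutation_importance(
                    model, fm.X, fm.y, n_repeats=5,
                    random_state=seed).importances_mean
            except Exception as exc:  # pragma: no cover
                raise CapabilityError(
                    f"{type(model).__name__} exposes no importance measure "
                    f"and permutation importance failed") from exc
    per_col = dict(zip(fm.X.columns, np.asarray(imp, dtype=float)))
    return {g: sum(per_col[c] for c in cols) for g, cols in fm.groups.items()}


def _cv_mae(factory: Callable, fm: FeatureMatrix, n_folds: int,
            seed: int) -> float:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = []
    X, y = fm.X.to_numpy(), fm.y.to_numpy()
    for tr, va in kf.split(X):
        model = factory()
        model.fit(X[tr], y[tr])
        pred = np.maximum(model.predict(X[va]), DURATION_BOUNDS[0])
        errs.append(np.mean(np.abs(pred - y[va])))
    return float(np.mean(errs))


def backward_eliminate(train: FeatureMatrix,
                       regressor_factory: Optional[Callable] = None,
                       max_features: int = 4, n_folds: int = 5,
                       seed: int = 0) -> SelectionTrace:
    """Wrapper backward elimination scored by cross-validated MAE.

    Starting from all feature groups, each round refits on the current set,
    scores it by k-fold MAE on the training split, and removes the group the
    fitted model ranks least important (ties broken toward the feature later
    in the schema order, for determinism). The selected set is the
    best-scoring one among those with at most ``max_features`` groups.
    """
    if regressor_factory is None:
        regressor_factory = lambda: make_regressor("gradient_boosted_trees",
                                                   seed)
    current = [g for g in FEATURE_GROUPS if g in train.groups]
    if len(current) < 1:
        raise ConfigurationError("no features to select from")
    trace = SelectionTrace()
    order = {g: i for i, g in enumerate(FEATURE_GROUPS)}
    while True:
        fm = train.restrict(current)
        mae = _cv_mae(regressor_factory, fm, n_folds, seed)
        trace.evaluated.append((tuple(current), mae))
        if len(current) == 1:
            break
        model = regressor_factory()
        model.fit(fm.X.to_numpy(), fm.y.to_numpy())
        imps = _group_importances(model, fm, seed)
        victim = min(current, key=lambda g: (imps[g], -order[g]))
        trace.steps.append((victim, mae))
        current.remove(victim)
    eligible = [(fs, mae) for fs, mae in trace.evaluated
                if len(fs) <= max_features]
    trace.selected_features = min(eligible, key=lambda t: t[1])[0]
    return trace


def _metrics(pred: np.ndarray, y: np.ndarray) -> tuple:
    err = np.asarray(pred, float) - np.asarray(y, float)
    return float(np.mean(np.abs(err))), float(np.mean(err ** 2))


def fit_predict(regressor_spec, train: FeatureMatrix, test: FeatureMatrix,
                seed: int = 0) -> tuple:
    """Fit on the training split only; report (predictions, MAE, MSE) on the
    held-out test split. Predictions are floored at the 2-minute minimum."""
    if callable(regressor_spec):
        model = regressor_spec()
    else:
        model = make_regressor(regressor_spec, seed)
    model.fit(train.X.to_numpy(), train.y.to_numpy())
    pred = np.maximum(model.predict(test.X.to_numpy()), DURATION_BOUNDS[0])
    mae, mse = _metrics(pred, test.y.to_numpy())
    return pred, mae, mse


def appointment_duration(predicted_minutes: float, mode: str) -> float:
    """Planned appointment length: predicted + 15-minute buffer, or the flat
    30-minute slot of the baseline."""
    if mode == "fixed":
        return FIXED_SLOT_MINUTES
    if mode == "predictive":
        if predicted_minutes is None or predicted_minutes <= 0:
            raise InvalidPredictionError(
                f"nonpositive predicted duration {predicted_minutes!r}")
        return float(predicted_minutes) + BUFFER_MINUTES
    raise ConfigurationError(f"unknown mode {mode!r}")


class DurationModel:
    """Train-once, predict-many wrapper around the pipeline above.

    Attributes
    ----------
    regressor_name : which estimator family backs the model.
    selected_features : feature groups in use (all of them when fitted with
        ``select=False``).
    trace : the SelectionTrace when wrapper selection ran, else None.
    """

    ARTIFACT_VERSION = 1

    def __init__(self, regressor_name: str = "gradient_boosted_trees",
                 seed: int = 0) -> None:
        self.regressor_name = regressor_name
        self.seed = seed
        self.selected_features: tuple = ()
        self.trace: Optional[SelectionTrace] = None
        self._model = None

    def fit(self, cohort: Sequence[Patient], select: bool = True,
            max_features: int = 4) -> "DurationModel":
        fm = clean(cohort_frame(cohort))
        if select:
            self.trace = backward_eliminate(
                fm, lambda: make_regressor(self.regressor_name, self.seed),
                max_features=max_features, seed=self.seed)
            self.selected_features = self.trace.selected_features
        else:
            self.selected_features = tuple(g for g in FEATURE_GROUPS
                                           if g in fm.groups)
        fm = fm.restrict(self.selected_features)
        self._model = make_regressor(self.regressor_name, self.seed)
        self._model.fit(fm.X.to_numpy(), fm.y.to_numpy())
        return self

    def predict(self, cohort: Sequence[Patient]) -> np.ndarray:
        if self._model is None:
            raise ConfigurationError("model not fitted")
        raw = cohort_frame(cohort)
        raw[LABEL] = 10.0  # dummy label, encoding only
        fm = _encode(raw).restrict(self.selected_features)
        return np.maximum(self._model.predict(fm.X.to_numpy()),
                          DURATION_BOUNDS[0])

    def annotate(self, cohort: Sequence[Patient]) -> None:
        """Fill ``predicted_procedure_minutes`` in place."""
        for p, yhat in zip(cohort, self.predict(cohort)):
            p.predicted_procedure_minutes = float(yhat)

    def save(self, path) -> None:
        payload = {"version": self.ARTIFACT_VERSION,
                   "regressor_name": self.regressor_name, "seed": self.seed,
                   "selected_features": self.selected_features,
                   "model": self._model}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "DurationModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != cls.ARTIFACT_VERSION:
            raise ConfigurationError("unsupported model artifact version")
        obj = cls(payload["regressor_name"], payload["seed"])
        obj.selected_features = tuple(payload["selected_features"])
        obj._model = payload["model"]
        return obj
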
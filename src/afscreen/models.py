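"""Gradient-boosted AF risk models with Bayesian hyperparameter search.

Both screening models (single-ECG and serial-ECG) are LightGBM classifiers
with a logistic objective, trained with early stopping on a patient-level
validation split and class weighting for the imbalanced AF label.  Model
selection maximizes validation AUROC over a bounded hyperparameter space
(number of estimators, learning rate, num_leaves, row/column subsampling,
min_data_in_leaf, positive-class weight) using Gaussian-process expected
improvement implemented on scikit-learn's ``GaussianProcessRegressor``.

Everything is deterministic under a fixed seed: single-threaded,
deterministic LightGBM, a seeded trial sequence, and a seeded acquisition
sampler.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.metrics import roc_auc_score

from .features import FEATURE_ORDER_VERSION

#: Bounded search space: name -> (low, high, kind) with kind in
#: {"int", "float", "logfloat"}.
DEFAULT_SPACE = {
    "n_estimators": (100, 2000, "int"),
    "learning_rate": (0.005, 0.3, "logfloat"),
    "num_leaves": (15, 255, "int"),
    "subsample": (0.5, 1.0, "float"),
    "colsample_bytree": (0.5, 1.0, "float"),
    "min_child_samples": (10, 200, "int"),
    "scale_pos_weight": (1.0, 20.0, "float"),
}

DEFAULT_FIXED_PARAMS = {
    "n_estimators": 400,
    "learning_rate": 0.05,
    "num_leaves": 31,
    "subsample": 0.9,
    "colsample_bytree": 0.9,
    "min_child_samples": 20,
}


@dataclass
class TrainingConfig:
    """Search bounds and budget for model development."""

    space: dict = field(default_factory=lambda: dict(DEFAULT_SPACE))
    n_trials: int = 10
    early_stopping_rounds: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        for name, (lo, hi, kind) in self.space.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")
            if kind not in ("int", "float", "logfloat"):
                raise ValueError(f"bad kind for {name}: {kind}")


def _to_unit(value: float, lo: float, hi: float, kind: str) -> float:
    if hi == lo:
        return 0.5
    if kind == "logfloat":
        return (np.log(value) - np.log(lo)) / (np.log(hi) - np.log(lo))
    return (value - lo) / (hi - lo)


def _from_unit(u: float, lo: float, hi: float, kind: str):
    u = float(np.clip(u, 0.0, 1.0))
    if kind == "logfloat":
        v = float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))) if hi > lo else lo
    else:
        v = lo + u * (hi - lo)
    v = min(max(v, lo), hi)  # guard float round-off at the bounds
    if kind == "int":
        v = int(round(v))
    return v


def bayes_optimize(
    objective,
    space: dict,
    n_trials: int,
    seed: int = 0,
    n_candidates: int = 256,
):
    """Maximize ``objective`` over a bounded space by GP expected improvement.

    ``objective`` maps a parameter dict to a scalar score (higher is
    better).  The first third of the budget (at least 3 trials, capped by
    the budget) is seeded random exploration; subsequent points maximize
    expected improvement of a Matern-5/2 Gaussian process over a random
    candidate set.  A failing trial is logged with ``status='failed'`` and
    the search continues.

    Returns ``(best_params, trials)`` where ``trials`` is the complete
    audit log (one entry per budgeted trial, failures included).
    """
    if n_trials < 1:
        raise ValueError("optimization budget must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(space.keys())
    dim = len(names)
    n_init = min(n_trials, max(3, n_trials // 3))

    trials: list[dict] = []
    units: list[np.ndarray] = []
    values: list[float] = []

    def run(u: np.ndarray) -> None:
        params = {
            n: _from_unit(u[i], *space[n]) for i, n in enumerate(names)
        }
        try:
            val = float(objective(params))
            status = "ok"
        except Exception as exc:  # noqa: BLE001 - failed trial is data
            val = np.nan
            status = f"failed: {type(exc).__name__}"
        trials.append({"trial": len(trials), "params": params, "value": val,
                       "status": status})
        if status == "ok" and np.isfinite(val):
            units.append(u)
            values.append(val)

    for _ in range(n_init):
        run(rng.random(dim))

    while len(trials) < n_trials:
        if len(values) < 2:
            run(rng.random(dim))
            continue
        X = np.vstack(units)
        y = np.asarray(values)
        kernel = Matern(
            length_scale=0.25 * np.ones(dim),
            length_scale_bounds=(1e-2, 1e2),
            nu=2.5,
        ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-9, 1e-1))
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=0, alpha=1e-8
        )
        with warnings.catch_warnings():
            # kernel hyperparameters hitting their bounds is routine here
            warnings.simplefilter("ignore")
            gp.fit(X, y)
        cand = rng.random((n_candidates, dim))
        # include local perturbations of the incumbent
        best_u = units[int(np.argmax(values))]
        local = np.clip(
            best_u + 0.05 * rng.standard_normal((32, dim)), 0.0, 1.0
        )
        cand = np.vstack([cand, local])
        mu, sigma = gp.predict(cand, return_std=True)
        best = y.max()
        xi = 1e-3
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best - xi) / sigma
            ei = (mu - best - xi) * norm.cdf(z) + sigma * norm.pdf(z)
        ei[sigma <= 0] = 0.0
        run(cand[int(np.argmax(ei))])

    if not values:
        raise RuntimeError("all optimization trials failed")
    ok = [t for t in trials if t["status"] == "ok" and np.isfinite(t["value"])]
    best_trial = max(ok, key=lambda t: t["value"])
    return best_trial["params"], trials


class AFRiskClassifier(BaseEstimator, ClassifierMixin):
    """LightGBM AF-risk classifier with optional Bayesian tuning.

    Parameters
    ----------
    n_trials : int
        Bayesian-optimization budget.  0 fits the fixed default
        hyperparameters directly (still with early stopping when a
        validation set is supplied).
    space : dict or None
        Search space ``{name: (low, high, kind)}``; defaults to
        :data:`DEFAULT_SPACE`.
    early_stopping_rounds : int
        Patience (boosting rounds) for validation-loss early stopping.
    random_state : int
        Seed for LightGBM, the trial sequence and the acquisition sampler.
    feature_order_version : str
        Version tag of the feature ordering this model was trained on;
        scoring data with a different version is a hard error.

    Fitted attributes (trailing underscore): ``model_``, ``best_params_``,
    ``validation_auroc_``, ``trials_``, ``feature_names_in_``, ``classes_``.
    """

    def __init__(
        self,
        n_trials: int = 0,
        space: dict | None = None,
        early_stopping_rounds: int = 30,
        random_state: int = 0,
        feature_order_version: str = FEATURE_ORDER_VERSION,
    ):
        self.n_trials = n_trials
        self.space = space
        self.early_stopping_rounds = early_stopping_rounds
        self.random_state = random_state
        self.feature_order_version = feature_order_version

    # -- helpers ---------------------------------------------------------
    def _validate_X(self, X, fitting: bool = False) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = list(X.columns)
            if fitting:
                self.feature_names_in_ = np.asarray(cols, dtype=object)
            elif hasattr(self, "feature_names_in_") and list(
                self.feature_names_in_
            ) != cols:
                raise ValueError(
                    "feature columns do not match the training order; "
                    "refusing to reorder silently"
                )
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        return X

    def _lgbm(self, params: dict) -> lgb.LGBMClassifier:
        return lgb.LGBMClassifier(
            objective="binary",
            random_state=self.random_state,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
            subsample_freq=1,
            **params,
        )

    def _fit_one(self, params, X, y, X_val, y_val):
        model = self._lgbm(params)
        if X_val is not None:
            model.fit(
                X,
                y,
                eval_set=[(X_val, y_val)],
                eval_metric="binary_logloss",
                callbacks=[
                    lgb.early_stopping(self.early_stopping_rounds, verbose=False),
                    lgb.log_evaluation(0),
                ],
            )
        else:
            model.fit(X, y)
        return model

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on training rows, early-stop / model-select on validation."""
        Xt = self._validate_X(X, fitting=True)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        self.n_features_in_ = Xt.shape[1]

        Xv = yv = None
        if X_val is not None:
            Xv = self._validate_X(X_val)
            yv = np.asarray(y_val).astype(int)

        pos = max(int(y.sum()), 1)
        default_spw = float((len(y) - pos) / pos)

        if self.n_trials and self.n_trials > 0:
            if Xv is None:
                raise ValueError("Bayesian search requires a validation set")
            space = self.space if self.space is not None else DEFAULT_SPACE

            def objective(params):
                m = self._fit_one(params, Xt, y, Xv, yv)
                return roc_auc_score(yv, m.predict_proba(Xv)[:, 1])

            best, trials = bayes_optimize(
                objective, space, self.n_trials, seed=self.random_state
            )
            self.best_params_ = best
            self.trials_ = trials
        else:
            self.best_params_ = dict(
                DEFAULT_FIXED_PARAMS, scale_pos_weight=default_spw
            )
            self.trials_ = []

        self.model_ = self._fit_one(self.best_params_, Xt, y, Xv, yv)
        if Xv is not None:
            self.validation_auroc_ = float(
                roc_auc_score(yv, self.model_.predict_proba(Xv)[:, 1])
            )
        else:
            self.validation_auroc_ = np.nan
        return self

    def predict_proba(self, X) -> np.ndarray:
        Xt = self._validate_X(X)
        return self.model_.predict_proba(Xt)

    def predict_score(self, X) -> np.ndarray:
        """AF risk score in [0, 1] for each row."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)


def _partition_hash(split) -> str:
    blob = "|".join(
        f"{pid}:{part}" for pid, part in sorted(split.assignment.items())
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def train(
    features: pd.DataFrame,
    labels: pd.Series,
    patient_ids: pd.Series,
    split,
    config: TrainingConfig | None = None,
) -> AFRiskClassifier:
    """Train a risk model on the train partition, tuned on validation.

    Rows are assigned to partitions through their patient id; test-partition
    rows are asserted never to enter the training or validation matrices
    (patient-level leakage guard).
    """
    config = config or TrainingConfig()
    patient_ids = pd.Series(np.asarray(patient_ids), index=features.index)
    labels = pd.Series(np.asarray(labels), index=features.index)
    part = patient_ids.map(split.assignment)
    if part.isna().any():
        raise ValueError("rows with patient ids missing from the split")
    train_mask = (part == "train").to_numpy()
    val_mask = (part == "validation").to_numpy()
    if not train_mask.any() or not val_mask.any():
        raise ValueError("train and validation partitions must be non-empty")

    test_ids = set(split.ids("test"))
    used = set(patient_ids[train_mask | val_mask])
    assert not (used & test_ids), "test patients leaked into development data"

    clf = AFRiskClassifier(
        n_trials=config.n_trials,
        space=config.space,
        early_stopping_rounds=config.early_stopping_rounds,
        random_state=config.seed,
    )
    clf.fit(
        features[train_mask],
        labels[train_mask],
        X_val=features[val_mask],
        y_val=labels[val_mask],
    )
    clf.partitions_hash_ = _partition_hash(split)
    return clf


def predict(model: AFRiskClassifier, features) -> np.ndarray:
    """Score rows with a trained model; scores are probabilities in [0, 1]."""
    return model.predict_score(features)
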
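"""The five per-segment apnea classifiers behind one train/predict contract.

Implementations delegate to scikit-learn and xgboost; this module owns the
fixed hyperparameter configurations and the uniform interface.  Printed
defaults: MLP hidden layer = 2 x n_features + 1, alpha 1, max_iter 1000;
SVM C 9.9, tol 5e-4; RF 148 trees, max_depth 185, max_features 15,
random_state 42; XGBoost eta 0.1, 10000 rounds with early stopping after 50,
max_depth 9, min_child_weight 0.121, gamma 6.45e-7, colsample_bytree 0.876,
subsample 0.872; LR random_state 42.  Hyperparameters not listed stay at the
library defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "train_classifier",
    "predict_segments",
    "save_model",
    "load_model",
    "KINDS",
]

KINDS = ("mlp", "svm", "rf", "xgb", "lr")

_ALIASES = {"xgboost": "xgb", "logistic": "lr", "randomforest": "rf"}


@dataclass(frozen=True)
class ClassifierConfig:
    """One of the five classifier kinds plus hyperparameter overrides."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        kind = _ALIASES.get(self.kind.lower(), self.kind.lower())
        object.__setattr__(self, "kind", kind)
        if kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected one of {KINDS}")


@dataclass
class TrainedModel:
    config: ClassifierConfig
    estimator: Any = field(repr=False)
    n_features_expected: int
    hyperparameters: dict[str, Any] = field(repr=False, default_factory=dict)


def _build_estimator(config: ClassifierConfig, n_features: int):
    kind, seed = config.kind, config.seed
    if kind == "mlp":
        params = dict(
            hidden_layer_sizes=(2 * n_features + 1,),
            alpha=1.0,
            max_iter=1000,
            random_state=seed,
        )
    elif kind == "svm":
        params = dict(C=9.9, tol=5e-4, probability=True, random_state=seed)
    elif kind == "rf":
        params = dict(
            n_estimators=148,
            max_depth=185,
            max_features=min(15, n_features),
            random_state=42,
        )
    elif kind == "xgb":
        params = dict(
            learning_rate=0.1,
            n_estimators=10000,
            early_stopping_rounds=50,
            max_depth=9,
            min_child_weight=0.121,
            gamma=6.45e-7,
            colsample_bytree=0.876,
            subsample=0.872,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    else:  # lr
        params = dict(random_state=42)
    params.update(config.params)
    cls = {
        "mlp": MLPClassifier,
        "svm": SVC,
        "rf": RandomForestClassifier,
        "xgb": XGBClassifier,
        "lr": LogisticRegression,
    }[kind]
    return cls(**params), params


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig,
    groups: np.ndarray | None = None,
) -> TrainedModel:
    """Fit one classifier on (already normalized, windowed) training rows.

    XGBoost's early stopping needs an evaluation set: 10% of the training
    rows are held out, grouped by recording when ``groups`` is given so no
    recording straddles the split.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    estimator, params = _build_estimator(config, X.shape[1])
    if config.kind == "xgb":
        if groups is not None and np.unique(groups).size >= 2:
            splitter = GroupShuffleSplit(n_splits=1, test_size=0.1, random_state=config.seed)
            fit_idx, eval_idx = next(splitter.split(X, y, groups))
        else:
            rng = np.random.default_rng(config.seed)
            perm = rng.permutation(len(y))
            n_eval = max(1, len(y) // 10)
            eval_idx, fit_idx = perm[:n_eval], perm[n_eval:]
        if np.unique(y[fit_idx]).size < 2:
            fit_idx, eval_idx = np.arange(len(y)), np.arange(len(y))
        estimator.fit(
            X[fit_idx], y[fit_idx], eval_set=[(X[eval_idx], y[eval_idx])], verbose=False
        )
    else:
        estimator.fit(X, y)
    return TrainedModel(
        config=config,
        estimator=estimator,
        n_features_expected=X.shape[1],
        hyperparameters={k: v for k, v in estimator.get_params().items()},
    )


def predict_segments(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment predictions: boolean labels and scores in [0, 1].

    Scores are class-1 probabilities (or calibrated surrogates); the label is
    ``score >= 0.5`` so label and score never disagree.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if X.shape[1] != model.n_features_expected:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features_expected}, "
            f"got {X.shape[1]}"
        )
    proba = model.estimator.predict_proba(X)
    classes = list(model.estimator.classes_)
    scores = proba[:, classes.index(True)]
    scores = np.clip(scores, 0.0, 1.0)
    return scores >= 0.5, scores


_SERIALIZATION_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Serialize a fitted model (version tag + config + fitted state)."""
    import pickle

    payload = {
        "version": _SERIALIZATION_VERSION,
        "config": model.config,
        "estimator": model.estimator,
        "n_features_expected": model.n_features_expected,
        "hyperparameters": model.hyperparameters,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> TrainedModel:
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != _SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model file version {payload.get('version')!r}")
    return TrainedModel(
        config=payload["config"],
        estimator=payload["estimator"],
        n_features_expected=payload["n_features_expected"],
        hyperparameters=payload["hyperparameters"],
    )
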
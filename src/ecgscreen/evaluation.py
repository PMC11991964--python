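"""Grouped cross-validation, detection metrics, AHI estimation and SAS diagnosis.

Per-segment detection is scored with ACC, SEN, SPE, PRE, F1 and AUC; screening
quality per recording comes from the apnea-hypopnea index AHI = 60/T x (number
of apneic minutes), T the annotated recording time in minutes, with sleep
apnea syndrome (SAS) called at AHI >= 5, and Pearson's r between predicted and
actual AHI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .classifiers import ClassifierConfig, train_classifier, predict_segments
from .features import normalize_features
from .windowing import WindowSpec, assemble_windowed_features

__all__ = [
    "ConfusionCounts",
    "CVSpec",
    "RecordingResult",
    "group_kfold_split",
    "segment_metrics",
    "compute_ahi",
    "diagnose_sas",
    "recording_metrics",
    "cross_validate_window",
    "run_experiment",
]

SAS_AHI_THRESHOLD = 5.0


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class CVSpec:
    """Grouped k-fold: every recording's segments stay in one fold."""

    n_folds: int = 5
    seed: int = 0


@dataclass
class RecordingResult:
    """Predicted vs actual screening outcome for one recording."""

    record_id: str
    T: int
    n_sa_pred: int
    n_sa_true: int
    predicted_ahi: float = field(init=False)
    actual_ahi: float = field(init=False)
    predicted_sas: bool = field(init=False)
    actual_sas: bool = field(init=False)

    def __post_init__(self) -> None:
        self.predicted_ahi = compute_ahi(self.n_sa_pred, self.T)
        self.actual_ahi = compute_ahi(self.n_sa_true, self.T)
        self.predicted_sas = diagnose_sas(self.predicted_ahi)
        self.actual_sas = diagnose_sas(self.actual_ahi)


def group_kfold_split(
    record_ids: Sequence[str], cv: CVSpec = CVSpec()
) -> list[tuple[list[str], list[str]]]:
    """Partition recordings into ``n_folds`` validation folds.

    Recordings are shuffled with the seeded generator and dealt round-robin,
    so 35 recordings give five validation folds of exactly 7.  Returns
    ``(train_ids, valid_ids)`` pairs; the folds partition the record set.
    """
    ids = list(record_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    if len(ids) < cv.n_folds:
        raise ValueError(f"need >= {cv.n_folds} records, got {len(ids)}")
    rng = np.random.default_rng(cv.seed)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    folds: list[list[str]] = [shuffled[k :: cv.n_folds] for k in range(cv.n_folds)]
    splits = []
    for k in range(cv.n_folds):
        valid = sorted(folds[k])
        train = sorted(set(ids) - set(valid))
        splits.append((train, valid))
    return splits


def confusion(true: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    true = np.asarray(true, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if true.shape != pred.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        TP=int(np.sum(true & pred)),
        TN=int(np.sum(~true & ~pred)),
        FP=int(np.sum(~true & pred)),
        FN=int(np.sum(true & ~pred)),
    )


def _classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    acc = ratio(c.TP + c.TN, c.total)
    sen = ratio(c.TP, c.TP + c.FN)
    spe = ratio(c.TN, c.TN + c.FP)
    pre = ratio(c.TP, c.TP + c.FP)
    f1 = (
        2 * pre * sen / (pre + sen)
        if np.isfinite(pre) and np.isfinite(sen) and (pre + sen) > 0
        else float("nan")
    )
    return {"ACC": acc, "SEN": sen, "SPE": spe, "PRE": pre, "F1": f1}


def segment_metrics(
    true: np.ndarray, pred: np.ndarray, scores: np.ndarray | None = None
) -> dict[str, float]:
    """ACC, SEN, SPE, PRE, F1 (and AUC when scores are given) for one fold.

    AUC uses the rank statistic with midranks for ties; it is undefined (and
    raises) when only one class is present in ``true``.
    """
    c = confusion(true, pred)
    out = _classification_metrics(c)
    out.update({"TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN})
    if scores is not None:
        true = np.asarray(true, dtype=bool)
        if np.unique(true).size < 2:
            raise ValueError("AUC undefined: a single class is present")
        out["AUC"] = float(roc_auc_score(true, np.asarray(scores, dtype=float)))
    return out


def compute_ahi(n_sa_segments: int, T: float) -> float:
    """Apnea-hypopnea index: 60/T x number of apneic minutes (events/hour)."""
    if T <= 0:
        raise ValueError(f"recording time must be positive, got {T}")
    if n_sa_segments < 0:
        raise ValueError("segment count must be non-negative")
    return 60.0 / T * n_sa_segments


def diagnose_sas(ahi: float, threshold: float = SAS_AHI_THRESHOLD) -> bool:
    """SAS screening decision: positive when AHI >= threshold (inclusive)."""
    if ahi < 0:
        raise ValueError("AHI cannot be negative")
    return bool(ahi >= threshold)


def recording_metrics(results: Sequence[RecordingResult]) -> dict[str, float]:
    """Per-recording SAS metrics plus Pearson's r between predicted/actual AHI."""
    if len(results) < 2:
        raise ValueError("need >= 2 recordings for per-recording metrics")
    true = np.array([r.actual_sas for r in results])
    pred = np.array([r.predicted_sas for r in results])
    out = _classification_metrics(confusion(true, pred))
    a = np.array([r.predicted_ahi for r in results])
    b = np.array([r.actual_ahi for r in results])
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson r undefined: an AHI vector has zero variance")
    out["r"] = float(stats.pearsonr(a, b).statistic)
    return out


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

def _check_disjoint(train_ids: Sequence[str], test_ids: Sequence[str]) -> None:
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"records present in both train and test: {sorted(overlap)}")


def _fit_predict(
    features: Mapping[str, pd.DataFrame],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    config: ClassifierConfig,
    spec: WindowSpec,
    edge_policy: str = "replicate",
):
    """Normalize on train, window, fit, and predict the test records."""
    _check_disjoint(train_ids, test_ids)
    train_df = pd.concat([features[r] for r in train_ids], ignore_index=True)
    norm_train, _, mean, scale = normalize_features(train_df)

    def apply_norm(rid: str) -> pd.DataFrame:
        df = features[rid].copy()
        cols = list(mean.index)
        df[cols] = ((df[cols] - mean) / scale).fillna(0.0)
        return df

    train_mats = {r: apply_norm(r) for r in train_ids}
    test_mats = {r: apply_norm(r) for r in test_ids}
    wtrain = assemble_windowed_features(train_mats, spec, edge_policy)
    wtest = assemble_windowed_features(test_mats, spec, edge_policy)
    model = train_classifier(wtrain.X, wtrain.y, config, groups=wtrain.groups)
    pred, scores = predict_segments(model, wtest.X)
    return model, wtest, pred, scores


def cross_validate_window(
    features: Mapping[str, pd.DataFrame],
    config: ClassifierConfig,
    spec: WindowSpec,
    cv: CVSpec,
    edge_policy: str = "replicate",
) -> float:
    """Mean per-segment accuracy of grouped k-fold CV for one window size."""
    accs = []
    for fold, (train_ids, valid_ids) in enumerate(
        group_kfold_split(sorted(features), cv)
    ):
        _, wvalid, pred, _ = _fit_predict(
            features, train_ids, valid_ids, config, spec, edge_policy
        )
        if np.unique(wvalid.y).size < 2:
            raise ValueError(f"fold {fold}: validation labels contain a single class")
        accs.append(float(np.mean(pred == wvalid.y)))
    return float(np.mean(accs))


def run_experiment(
    features: Mapping[str, pd.DataFrame],
    config: ClassifierConfig,
    spec: WindowSpec,
    split: tuple[Sequence[str], Sequence[str]] | CVSpec,
    edge_policy: str = "replicate",
) -> dict:
    """Full screening experiment for one classifier and window size.

    ``split`` is either ``(train_ids, test_ids)`` for the independent-test
    protocol or a :class:`CVSpec` for grouped cross-validation (each record
    is scored in the fold where it is held out).  Returns per-segment
    metrics, per-recording SAS metrics, the per-record AHI pairs, and a run
    log with every hyperparameter actually used.
    """
    if isinstance(split, CVSpec):
        partitions = group_kfold_split(sorted(features), split)
        mode = "cv"
    else:
        train_ids, test_ids = split
        partitions = [(list(train_ids), list(test_ids))]
        mode = "train_test"

    all_true, all_pred, all_scores = [], [], []
    rec_results: list[RecordingResult] = []
    log_models = []
    for train_ids, test_ids in partitions:
        model, wtest, pred, scores = _fit_predict(
            features, train_ids, test_ids, config, spec, edge_policy
        )
        all_true.append(wtest.y)
        all_pred.append(pred)
        all_scores.append(scores)
        log_models.append(model.hyperparameters)
        for rid in test_ids:
            mask = wtest.groups == rid
            rec_results.append(
                RecordingResult(
                    record_id=rid,
                    T=int(mask.sum()),
                    n_sa_pred=int(pred[mask].sum()),
                    n_sa_true=int(wtest.y[mask].sum()),
                )
            )

    y = np.concatenate(all_true)
    p = np.concatenate(all_pred)
    s = np.concatenate(all_scores)
    report = {
        "mode": mode,
        "window": {"past": spec.past, "future": spec.future},
        "classifier": config.kind,
        "segment_metrics": segment_metrics(y, p, s),
        "recording_metrics": recording_metrics(rec_results),
        "recordings": [
            {
                "record_id": r.record_id,
                "T": r.T,
                "n_sa_pred": r.n_sa_pred,
                "n_sa_true": r.n_sa_true,
                "predicted_ahi": r.predicted_ahi,
                "actual_ahi": r.actual_ahi,
                "predicted_sas": r.predicted_sas,
                "actual_sas": r.actual_sas,
            }
            for r in rec_results
        ],
        "run_log": {
            "seed": config.seed,
            "edge_policy": edge_policy,
            "n_records": len(features),
            "hyperparameters": log_models[0],
        },
    }
    return report
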
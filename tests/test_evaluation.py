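"""Metric formulas, AUC oracle equivalence, AHI/SAS rules and CV integrity."""

import numpy as np
import pandas as pd
import pytest

from ecgscreen import (
    ClassifierConfig,
    CVSpec,
    RecordingResult,
    WindowSpec,
    compute_ahi,
    diagnose_sas,
    group_kfold_split,
    recording_metrics,
    run_experiment,
    segment_metrics,
)
from ecgscreen.features import FEATURE_COLUMNS, FEATURE_NAMES


def brute_force_auc(y, scores):
    """Pairwise-comparison probability with midrank tie handling."""
    pos = [s for t, s in zip(y, scores) if t]
    neg = [s for t, s in zip(y, scores) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSegmentMetrics:
    def test_printed_equations_on_fixed_confusion(self):
        y = np.array([True] * 100 + [False] * 100)
        pred = np.array([True] * 84 + [False] * 16 + [True] * 10 + [False] * 90)
        m = segment_metrics(y, pred)
        assert m["ACC"] == pytest.approx(0.87)
        assert m["SEN"] == pytest.approx(0.84)
        assert m["SPE"] == pytest.approx(0.90)
        assert m["PRE"] == pytest.approx(84 / 94, abs=1e-9)
        assert m["F1"] == pytest.approx(2 * (84 / 94) * 0.84 / (84 / 94 + 0.84), abs=1e-9)
        assert (m["TP"], m["FN"], m["FP"], m["TN"]) == (84, 16, 10, 90)

    def test_perfect_predictions(self):
        y = np.array([True, False, True, False])
        m = segment_metrics(y, y, scores=y.astype(float))
        assert all(m[k] == 1.0 for k in ("ACC", "SEN", "SPE", "PRE", "F1", "AUC"))

    def test_auc_extremes(self):
        y = np.array([True, False, True, False])
        assert segment_metrics(y, y, scores=y.astype(float))["AUC"] == 1.0
        assert segment_metrics(y, y, scores=1.0 - y.astype(float))["AUC"] == 0.0

    def test_auc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            m = segment_metrics(y, scores >= 0.5, scores)
            assert m["AUC"] == pytest.approx(brute_force_auc(y, scores), abs=1e-12)

    def test_metric_identities_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            y = rng.random(50) < rng.uniform(0.2, 0.8)
            pred = rng.random(50) < 0.5
            if y.all() or not y.any():
                continue
            m = segment_metrics(y, pred)
            total = m["TP"] + m["TN"] + m["FP"] + m["FN"]
            assert total == 50
            assert m["ACC"] == pytest.approx((m["TP"] + m["TN"]) / total)
            for k in ("ACC", "SEN", "SPE"):
                assert 0.0 <= m[k] <= 1.0

    def test_single_class_auc_undefined(self):
        y = np.ones(5, dtype=bool)
        with pytest.raises(ValueError, match="single class"):
            segment_metrics(y, y, scores=np.ones(5))


class TestAhiSas:
    @pytest.mark.parametrize(
        "n_sa, T, expected", [(40, 480, 5.0), (0, 400, 0.0), (70, 420, 10.0)]
    )
    def test_ahi_formula(self, n_sa, T, expected):
        assert compute_ahi(n_sa, T) == expected

    def test_ahi_scale_invariance(self):
        assert compute_ahi(40, 480) == compute_ahi(80, 960)

    def test_ahi_requires_positive_time(self):
        with pytest.raises(ValueError):
            compute_ahi(10, 0)

    @pytest.mark.parametrize("ahi, expected", [(5.0, True), (4.99, False), (0.0, False)])
    def test_sas_threshold_inclusive(self, ahi, expected):
        assert diagnose_sas(ahi) is expected


class TestGroupKFold:
    def test_thirty_five_records_give_folds_of_seven(self):
        ids = [f"rec{i:02d}" for i in range(35)]
        splits = group_kfold_split(ids, CVSpec(seed=4))
        assert len(splits) == 5
        valid_sets = [set(v) for _, v in splits]
        assert all(len(v) == 7 for v in valid_sets)
        assert all(len(t) == 28 for t, _ in splits)
        # folds partition the record set: no id in two validation folds
        union = set().union(*valid_sets)
        assert union == set(ids)
        assert sum(len(v) for v in valid_sets) == 35
        for train, valid in splits:
            assert not set(train) & set(valid)

    def test_ten_records_give_folds_of_two(self):
        splits = group_kfold_split([f"r{i}" for i in range(10)], CVSpec(seed=0))
        assert all(len(v) == 2 for _, v in splits)

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="need >="):
            group_kfold_split(["a", "b"], CVSpec())


class TestRecordingMetrics:
    def test_identity_predictions(self):
        results = [
            RecordingResult(f"r{i}", T=480, n_sa_pred=n, n_sa_true=n)
            for i, n in enumerate([10, 50, 100, 200])
        ]
        m = recording_metrics(results)
        assert m["r"] == pytest.approx(1.0)
        assert m["ACC"] == 1.0

    def test_all_positive_predictions(self):
        # every prediction crosses the SAS threshold, truth is half negative
        results = [
            RecordingResult(f"r{i}", T=60, n_sa_pred=p, n_sa_true=t)
            for i, (p, t) in enumerate([(30, 30), (40, 40), (6, 1), (7, 2)])
        ]
        m = recording_metrics(results)
        assert m["SEN"] == 1.0
        assert m["SPE"] == 0.0

    def test_pearson_matches_hand_computation(self):
        pairs = [(4, 6), (10, 12), (20, 15), (30, 28)]  # (pred, true) AHI at T=60
        results = [
            RecordingResult(f"r{i}", T=60, n_sa_pred=p, n_sa_true=t)
            for i, (p, t) in enumerate(pairs)
        ]
        a = np.array([p for p, _ in pairs], float)
        b = np.array([t for _, t in pairs], float)
        hand = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert recording_metrics(results)["r"] == pytest.approx(hand, abs=1e-12)

    def test_zero_variance_rejected(self):
        results = [
            RecordingResult(f"r{i}", T=60, n_sa_pred=10, n_sa_true=i) for i in range(3)
        ]
        with pytest.raises(ValueError, match="zero variance"):
            recording_metrics(results)


def synthetic_feature_frames(n_records=8, n_minutes=30, seed=0):
    """Feature tables where one feature carries the label (fast, no signals)."""
    rng = np.random.default_rng(seed)
    frames = {}
    for i in range(n_records):
        rid = f"r{i}"
        labels = rng.random(n_minutes) < 0.4
        data = {
            "record_id": rid,
            "minute_index": np.arange(n_minutes),
            "label": labels,
        }
        for j, name in enumerate(FEATURE_NAMES):
            signal = labels.astype(float) if j < 4 else 0.0
            data[name] = signal + rng.normal(0, 0.3, size=n_minutes)
        data["valid"] = True
        frames[rid] = pd.DataFrame(data, columns=FEATURE_COLUMNS)
    return frames


class TestRunExperiment:
    def test_train_test_report_structure(self):
        frames = synthetic_feature_frames()
        ids = sorted(frames)
        report = run_experiment(
            frames, ClassifierConfig("lr"), WindowSpec(1, 1), (ids[:6], ids[6:])
        )
        assert report["mode"] == "train_test"
        assert set(report["segment_metrics"]) >= {"ACC", "SEN", "SPE", "PRE", "F1", "AUC"}
        assert len(report["recordings"]) == 2
        for rec in report["recordings"]:
            assert rec["predicted_ahi"] == pytest.approx(
                60.0 / rec["T"] * rec["n_sa_pred"]
            )
        # the run log records the hyperparameters actually used
        assert report["run_log"]["hyperparameters"]["random_state"] == 42

    def test_leakage_probe_errors(self):
        frames = synthetic_feature_frames()
        ids = sorted(frames)
        with pytest.raises(ValueError, match="both train and test"):
            run_experiment(
                frames, ClassifierConfig("lr"), WindowSpec(0, 0), (ids[:6], ids[5:])
            )

    def test_cv_mode_scores_every_record_once(self):
        frames = synthetic_feature_frames()
        report = run_experiment(
            frames, ClassifierConfig("lr"), WindowSpec(0, 0), CVSpec(n_folds=4, seed=1)
        )
        scored = [r["record_id"] for r in report["recordings"]]
        assert sorted(scored) == sorted(frames)
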
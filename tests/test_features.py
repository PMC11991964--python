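"""Feature formulas against brute-force oracles, spectral band placement, normalization."""

import numpy as np
import pandas as pd
import pytest

from ecgscreen import (
    BandDefinition,
    MinuteLabels,
    RPeakSeries,
    SpectralEstimatorSpec,
    band_powers,
    extract_recording_features,
    normalize_features,
    segment_beats,
    time_domain_features,
)
from ecgscreen.features import FEATURE_NAMES


def brute_force_time_domain(rr):
    """Naive loop implementation of the six time-domain features."""
    n = len(rr)
    mrr = sum(rr) / n
    mhr = sum(60000.0 / x for x in rr) / n
    sq = [(rr[i + 1] - rr[i]) ** 2 for i in range(n - 1)]
    rmssd = (sum(sq) / len(sq)) ** 0.5
    sdnn = (sum((x - mrr) ** 2 for x in rr) / n) ** 0.5
    nn50 = sum(1 for i in range(n - 1) if abs(rr[i + 1] - rr[i]) > 50.0)
    return {
        "MRR": mrr,
        "MHR": mhr,
        "RMSSD": rmssd,
        "SDNN": sdnn,
        "NN50": float(nn50),
        "pNN50": nn50 / n,
    }


class TestTimeDomain:
    def test_constant_series(self):
        out = time_domain_features([800.0, 800.0, 800.0])
        assert out == {
            "MRR": 800.0,
            "MHR": 75.0,
            "RMSSD": 0.0,
            "SDNN": 0.0,
            "NN50": 0.0,
            "pNN50": 0.0,
        }

    def test_hand_computed_examples(self):
        out = time_domain_features([800.0, 850.0, 790.0])
        assert out["RMSSD"] == pytest.approx(np.sqrt((50**2 + 60**2) / 2), abs=1e-9)
        assert out["SDNN"] == pytest.approx(26.246693443487, abs=1e-6)

        out = time_domain_features([800.0, 860.0, 900.0, 920.0])
        assert out["NN50"] == 1.0
        assert out["pNN50"] == 0.25  # divisor is the number of RR intervals

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            rr = rng.uniform(400, 1500, size=rng.integers(2, 120)).tolist()
            fast = time_domain_features(rr)
            slow = brute_force_time_domain(rr)
            for k in fast:
                assert fast[k] == pytest.approx(slow[k], rel=1e-9, abs=1e-12), k

    def test_single_interval_rejected(self):
        with pytest.raises(ValueError):
            time_domain_features([800.0])

    def test_sample_sd_variant(self):
        rr = [800.0, 850.0, 790.0]
        assert time_domain_features(rr, sample_sd=True)["SDNN"] == pytest.approx(
            np.std(rr, ddof=1), abs=1e-12
        )


def _beat_series(freq, amplitude=50.0, mean=800.0, seconds=60.0, dt=0.8):
    times = np.arange(0.0, seconds, dt)
    values = mean + amplitude * np.sin(2 * np.pi * freq * times)
    return times, values


def periodogram_band_fractions(times, values, bands=BandDefinition()):
    """Independent oracle: plain periodogram on the same 3 Hz cubic-interp grid."""
    from scipy.interpolate import interp1d

    fs = 3.0
    n = int(np.floor((times[-1] - times[0]) * fs)) + 1
    grid = times[0] + np.arange(n) / fs
    x = interp1d(times, values, kind="cubic")(grid)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x, 256)) ** 2
    freqs = np.fft.rfftfreq(256, 1 / fs)
    out = {}
    for name, (lo, hi) in (("VLF", bands.vlf), ("LF", bands.lf), ("HF", bands.hf)):
        out[name] = spec[(freqs >= lo) & (freqs < hi)].sum()
    return out


class TestBandPowers:
    def test_lf_sinusoid_lands_in_lf(self):
        times, values = _beat_series(0.10)
        p = band_powers(times, values)
        assert p["LF"] / (p["VLF"] + p["LF"] + p["HF"]) >= 0.9
        oracle = periodogram_band_fractions(times, values)
        assert oracle["LF"] / sum(oracle.values()) >= 0.9

    def test_hf_sinusoid_lands_in_hf(self):
        times, values = _beat_series(0.25)
        p = band_powers(times, values)
        assert p["HF_norm"] >= 0.9
        assert p["LF_norm"] <= 0.1

    def test_constant_series_zero_power_rule(self):
        times = np.arange(0.0, 60.0, 0.8)
        p = band_powers(times, np.full_like(times, 800.0))
        assert p["VLF"] == p["LF"] == p["HF"] == 0.0
        assert p["LF_HF"] == p["LF_norm"] == p["HF_norm"] == 0.0

    def test_norms_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            times = np.sort(rng.uniform(0, 60, size=70))
            values = 800 + rng.normal(0, 40, size=70)
            p = band_powers(times, values)
            if p["LF"] + p["HF"] > 0:
                assert p["LF_norm"] + p["HF_norm"] == pytest.approx(1.0, abs=1e-9)

    def test_band_energy_bounded_by_total(self):
        rng = np.random.default_rng(4)
        times = np.sort(rng.uniform(0, 60, size=80))
        values = 800 + rng.normal(0, 40, size=80)
        p = band_powers(times, values)
        from scipy.interpolate import interp1d
        from scipy.signal import welch

        fs = 3.0
        n = int(np.floor((times[-1] - times[0]) * fs)) + 1
        grid = times[0] + np.arange(n) / fs
        x = interp1d(times, values, kind="cubic")(grid)
        x = x - x.mean()
        f, psd = welch(x, fs=fs, window="hamming", nperseg=n, nfft=256,
                       noverlap=0, detrend=False)
        total = psd.sum() * fs / 256
        assert p["VLF"] + p["LF"] + p["HF"] <= total + 1e-9

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="30 s"):
            band_powers([0.0, 1.0, 2.0, 3.0], [800.0] * 4)

    def test_literal_ratio_variant(self):
        """The algebraically literal amplitude ratios: LF/(LF/HF) == HF."""
        times, values = _beat_series(0.25)
        literal = band_powers(times, values, SpectralEstimatorSpec(literal_ratio=True))
        assert literal["LF_norm"] == pytest.approx(literal["HF"], rel=1e-12)


def _uniform_series(n_minutes=3, step=1.0, start=0.5):
    times = np.arange(start, n_minutes * 60.0, step)
    rr = np.diff(times) * 1000.0
    return RPeakSeries("r", times, np.ones_like(times), rr, corrected_rr=rr)


class TestSegmentBeats:
    def test_terminating_peak_rule(self):
        series = _uniform_series()
        rr, rr_t, amp, amp_t = segment_beats(series, 0)
        assert amp.size == 60  # peaks at 0.5 .. 59.5 s
        assert rr.size == 59  # the interval ending at 60.5 s belongs to minute 1
        assert np.all((rr_t >= 0) & (rr_t < 60))

    def test_partition_property(self):
        series = _uniform_series()
        total_amp = sum(segment_beats(series, m)[2].size for m in range(3))
        assert total_amp == series.peak_times.size
        total_rr = sum(segment_beats(series, m)[0].size for m in range(3))
        assert total_rr == series.rr_intervals.size

    def test_empty_minute(self):
        series = _uniform_series(n_minutes=1)
        rr, _, amp, _ = segment_beats(series, 5)
        assert rr.size == 0 and amp.size == 0


class TestExtraction:
    def test_shape_and_validity(self, clean_record):
        from ecgscreen import preprocess_record

        series = preprocess_record(clean_record.record)
        table = extract_recording_features(series, clean_record.labels)
        assert table.shape[0] == clean_record.labels.n_segments
        assert table["valid"].all()
        assert np.isfinite(table[FEATURE_NAMES].to_numpy()).all()
        assert len(FEATURE_NAMES) == 18

    def test_sparse_minute_marked_invalid(self):
        times = np.array([0.5, 1.5, 30.0, 65.0, 66.0, 67.0, 68.0])
        rr = np.diff(times) * 1000.0
        series = RPeakSeries("r", times, np.ones_like(times), rr, corrected_rr=rr)
        labels = MinuteLabels("r", np.array([False, False]))
        table = extract_recording_features(series, labels)
        assert not table["valid"].any()
        assert table[FEATURE_NAMES].isna().all().all()

    def test_record_mismatch(self, clean_record):
        from ecgscreen import preprocess_record

        series = preprocess_record(clean_record.record)
        labels = MinuteLabels("other", clean_record.labels.labels)
        with pytest.raises(ValueError, match="mismatch"):
            extract_recording_features(series, labels)


class TestNormalization:
    def _frame(self, col):
        data = {name: col for name in FEATURE_NAMES}
        return pd.DataFrame(data)

    def test_two_point_zscore(self):
        train, _, mean, scale = normalize_features(self._frame([1.0, 3.0]))
        assert train[FEATURE_NAMES[0]].tolist() == [-1.0, 1.0]
        assert mean.iloc[0] == 2.0 and scale.iloc[0] == 1.0

    def test_constant_column_scale_one(self):
        train, _, _, scale = normalize_features(self._frame([5.0, 5.0, 5.0]))
        assert (train[FEATURE_NAMES] == 0).all().all()
        assert (scale == 1.0).all()

    def test_apply_uses_train_statistics(self):
        train = self._frame([1.0, 3.0])
        apply_to = self._frame([2.0, 4.0])
        _, normed, _, _ = normalize_features(train, apply_to)
        assert normed[FEATURE_NAMES[0]].tolist() == [0.0, 2.0]

    def test_normalized_train_is_standardized(self):
        rng = np.random.default_rng(9)
        train = pd.DataFrame({n: rng.normal(5, 3, size=200) for n in FEATURE_NAMES})
        normed, _, _, _ = normalize_features(train)
        assert np.allclose(normed[FEATURE_NAMES].mean(), 0.0, atol=1e-9)
        assert np.allclose(normed[FEATURE_NAMES].std(ddof=0), 1.0, atol=1e-9)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            normalize_features(self._frame([]))
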
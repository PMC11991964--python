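"""Per-minute HRV and R-amplitude features.

Eighteen features per annotated 1-min segment: six time-domain RR features
(MRR, MHR, RMSSD, SDNN, NN50, pNN50), six frequency-domain RR features and six
frequency-domain R-amplitude features (VLF/LF/HF band powers plus LF/HF,
LF/(LF+HF), HF/(LF+HF)).  Spectra come from a Welch/modified-periodogram
estimate on the beat series cubic-interpolated to a uniform 3 Hz grid, FFT
length 256.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal as sps

from .ecg_io import MinuteLabels
from .preprocess import RPeakSeries

__all__ = [
    "BandDefinition",
    "SpectralEstimatorSpec",
    "FEATURE_NAMES",
    "FEATURE_COLUMNS",
    "segment_beats",
    "time_domain_features",
    "band_powers",
    "extract_recording_features",
    "normalize_features",
]


@dataclass(frozen=True)
class BandDefinition:
    """Half-open [lo, hi) frequency bands in Hz for VLF, LF and HF power."""

    vlf: tuple[float, float] = (0.0, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        if not (self.vlf[1] == self.lf[0] and self.lf[1] == self.hf[0]):
            raise ValueError("bands must be contiguous and non-overlapping")


@dataclass(frozen=True)
class SpectralEstimatorSpec:
    """Welch-estimator settings for the beat-series spectra.

    A 1-min segment resampled at 3 Hz yields fewer points than the 256-point
    FFT, so the estimate degenerates to a single zero-padded modified
    periodogram — deterministic and therefore easy to test.
    ``literal_ratio`` selects the algebraically literal amplitude-ratio
    variant LF/(LF/HF), HF/(LF/HF) instead of the normalized powers.
    """

    resample_rate: float = 3.0
    fft_length: int = 256
    window_function: str = "hamming"
    detrend: bool = True
    literal_ratio: bool = False


RR_TIME_NAMES = ["MRR", "MHR", "RMSSD", "SDNN", "NN50", "pNN50"]
FREQ_NAMES = ["VLF", "LF", "HF", "LF_HF", "LF_norm", "HF_norm"]
FEATURE_NAMES = (
    RR_TIME_NAMES
    + [f"rr_{n}" for n in FREQ_NAMES]
    + [f"amp_{n}" for n in FREQ_NAMES]
)
FEATURE_COLUMNS = ["record_id", "minute_index", "label"] + FEATURE_NAMES + ["valid"]


def segment_beats(
    series: RPeakSeries, minute_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Beats of one 1-min segment: ``(rr_ms, rr_times, amplitudes, amp_times)``.

    An RR interval belongs to the minute containing its terminating R peak;
    amplitudes belong to the minute containing their peak.  Both use the
    half-open window ``[60 m, 60 (m+1))`` seconds.
    """
    t0, t1 = 60.0 * minute_index, 60.0 * (minute_index + 1)
    times = series.peak_times
    rr = series.corrected_rr if series.corrected_rr.size else series.rr_intervals
    term_times = times[1:]  # time of the peak terminating each interval
    rr_mask = (term_times >= t0) & (term_times < t1)
    amp_mask = (times >= t0) & (times < t1)
    return (
        rr[rr_mask],
        term_times[rr_mask],
        series.peak_amplitudes[amp_mask],
        times[amp_mask],
    )


def time_domain_features(rr: np.ndarray, sample_sd: bool = False) -> dict[str, float]:
    """Six time-domain HRV features from an RR series in ms.

    SDNN is the population (divide-by-N) standard deviation unless
    ``sample_sd`` asks for the N-1 variant; NN50 counts successive
    differences strictly exceeding 50 ms and pNN50 divides by the number of
    RR intervals.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    diffs = np.diff(rr)
    nn50 = int(np.sum(np.abs(diffs) > 50.0))
    return {
        "MRR": float(np.mean(rr)),
        "MHR": float(np.mean(60000.0 / rr)),
        "RMSSD": float(np.sqrt(np.mean(diffs**2))),
        "SDNN": float(np.std(rr, ddof=1 if sample_sd else 0)),
        "NN50": float(nn50),
        "pNN50": float(nn50 / rr.size),
    }


def band_powers(
    times: np.ndarray,
    values: np.ndarray,
    estimator: SpectralEstimatorSpec = SpectralEstimatorSpec(),
    bands: BandDefinition = BandDefinition(),
) -> dict[str, float]:
    """Band powers and ratios of an irregularly sampled beat series.

    The series is cubic-interpolated onto a uniform grid at
    ``estimator.resample_rate`` spanning the beat times, mean-removed, and a
    zero-padded Welch estimate of length ``fft_length`` integrates to the
    band powers over the half-open VLF/LF/HF intervals.  If LF+HF power is
    zero, all ratios are defined as 0 (degenerate-segment rule).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 4 or times[-1] - times[0] < 30.0:
        raise ValueError("need >= 4 beats spanning >= 30 s for spectral estimation")
    fs = estimator.resample_rate
    if np.ptp(values) == 0:
        # constant series: mean removal annihilates it exactly
        return {k: 0.0 for k in ("VLF", "LF", "HF", "LF_HF", "LF_norm", "HF_norm")}
    n_grid = int(np.floor((times[-1] - times[0]) * fs)) + 1
    grid = times[0] + np.arange(n_grid) / fs
    resampled = interpolate.interp1d(times, values, kind="cubic")(grid)
    if estimator.detrend:
        resampled = resampled - resampled.mean()
    freqs, psd = sps.welch(
        resampled,
        fs=fs,
        window=estimator.window_function,
        nperseg=min(n_grid, estimator.fft_length),
        nfft=estimator.fft_length,
        noverlap=0,
        detrend=False,
        scaling="density",
    )
    df = fs / estimator.fft_length

    def band_power(band: tuple[float, float]) -> float:
        mask = (freqs >= band[0]) & (freqs < band[1])
        return float(np.sum(psd[mask]) * df)

    vlf, lf, hf = (band_power(b) for b in (bands.vlf, bands.lf, bands.hf))
    if lf + hf > 0:
        lf_hf = lf / hf if hf > 0 else 0.0
        if estimator.literal_ratio:
            # literal reading of LF/(LF/HF) and HF/(LF/HF)
            lf_norm = lf / lf_hf if lf_hf > 0 else 0.0
            hf_norm = hf / lf_hf if lf_hf > 0 else 0.0
        else:
            lf_norm = lf / (lf + hf)
            hf_norm = hf / (lf + hf)
    else:
        lf_hf = lf_norm = hf_norm = 0.0
    return {
        "VLF": vlf,
        "LF": lf,
        "HF": hf,
        "LF_HF": lf_hf,
        "LF_norm": lf_norm,
        "HF_norm": hf_norm,
    }


def extract_recording_features(
    series: RPeakSeries,
    labels: MinuteLabels,
    estimator: SpectralEstimatorSpec = SpectralEstimatorSpec(),
    bands: BandDefinition = BandDefinition(),
    min_beats: int = 10,
) -> pd.DataFrame:
    """One 18-feature row per annotated minute, in minute order.

    Segments with fewer than ``min_beats`` beats (or too short a beat span for
    spectral estimation) are kept in the grid with ``valid=False`` and NaN
    features; they are imputed with training-set means downstream so the AHI
    denominator still covers every annotated minute.
    """
    if series.record_id != labels.record_id:
        raise ValueError(
            f"record mismatch: peaks from {series.record_id!r}, "
            f"labels from {labels.record_id!r}"
        )
    rows = []
    for m in range(labels.n_segments):
        rr, rr_t, amp, amp_t = segment_beats(series, m)
        row: dict[str, object] = {
            "record_id": series.record_id,
            "minute_index": m,
            "label": bool(labels.labels[m]),
        }
        valid = (
            rr.size >= max(min_beats, 2)
            and amp.size >= max(min_beats, 4)
            and rr_t.size >= 4
            and rr_t[-1] - rr_t[0] >= 30.0
            and amp_t[-1] - amp_t[0] >= 30.0
        )
        if valid:
            row.update(time_domain_features(rr))
            row.update(
                {f"rr_{k}": v for k, v in band_powers(rr_t, rr, estimator, bands).items()}
            )
            row.update(
                {f"amp_{k}": v for k, v in band_powers(amp_t, amp, estimator, bands).items()}
            )
        else:
            row.update({name: np.nan for name in FEATURE_NAMES})
        row["valid"] = bool(valid)
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def normalize_features(
    train: pd.DataFrame, apply_to: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.Series, pd.Series]:
    """Z-score feature columns with training-set mean and population SD.

    Statistics ignore NaN (invalid) segments; after scaling, NaNs are imputed
    with 0, i.e. the training mean.  Constant columns get scale 1 so they map
    to all-zeros.  Returns ``(train_norm, apply_norm, mean, scale)``; the same
    transform is applied to ``apply_to`` so no test-set statistics leak in.
    """
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to normalize")
    cols = [c for c in FEATURE_NAMES if c in train.columns]
    mean = train[cols].mean(skipna=True)
    scale = train[cols].std(ddof=0, skipna=True)
    scale = scale.where(scale > 0, 1.0).fillna(1.0)
    mean = mean.fillna(0.0)

    def transform(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out[cols] = ((df[cols] - mean) / scale).fillna(0.0)
        return out

    return transform(train), (None if apply_to is None else transform(apply_to)), mean, scale
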
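"""Labeled synthetic single-lead ECG recordings with apnea-dependent dynamics.

The generator plants the physiological signatures the screening pipeline must
find.  Normal minutes carry respiratory sinus arrhythmia: an HF-band (0.25 Hz)
oscillation of the RR tachogram.  Apneic minutes carry the cyclical variation
of heart rate that accompanies repetitive apneas: a slow (0.025 Hz)
bradycardia-tachycardia oscillation, plus modulation of the R-peak amplitude
at the same rate.  Apnea occurs in contiguous multi-minute episodes, and the
modulation envelope ramps in and out with a first-order time constant rather
than switching instantaneously — transitions between breathing states are
gradual, so minutes at episode edges are genuinely ambiguous on their own and
neighbouring minutes carry usable context.

The rendered ECG places a Gaussian-bump PQRST template at each beat and adds
baseline wander (0.3 Hz), powerline hum (50 Hz) and broadband noise, sampled
at 100 Hz / 16-bit like overnight screening recordings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .ecg_io import (
    ECGRecord,
    MinuteLabels,
    write_minute_annotations,
    write_wfdb_record,
)

__all__ = [
    "SynthConfig",
    "SynthRecord",
    "simulate_labels",
    "simulate_rr",
    "render_ecg",
    "generate_record",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults emulate overnight screening conditions.

    Amplitudes are in ms (RR modulation) or mV (signal-level terms); episode
    lengths are inclusive uniform-integer ranges in minutes.
    """

    n_records: int = 20
    minutes_per_record: int = 60
    normal_episode_minutes: tuple[int, int] = (2, 8)
    apnea_episode_minutes: tuple[int, int] = (2, 6)
    apnea_fraction_bounds: tuple[float, float] = (0.1, 0.7)
    healthy_fraction: float = 0.35
    healthy_normal_episode_minutes: tuple[int, int] = (15, 30)
    healthy_apnea_episode_minutes: tuple[int, int] = (1, 2)
    healthy_apnea_fraction_bounds: tuple[float, float] = (0.0, 0.06)
    baseline_rr_ms: float = 850.0
    baseline_rr_jitter_ms: float = 60.0   # between-record spread
    rsa_amplitude_ms: float = 30.0
    rsa_freq_hz: float = 0.25
    cvhr_amplitude_ms: float = 120.0
    cvhr_freq_hz: float = 0.025
    transition_tau_s: float = 45.0        # apnea envelope ramp time constant
    rr_jitter_ms: float = 25.0            # per-beat white jitter
    rr_clip_ms: tuple[float, float] = (400.0, 1800.0)
    amp_modulation_depth: float = 0.2
    ecg_amplitude_mv: float = 1.0
    noise_sd: float = 0.03
    wander_amplitude: float = 0.10
    wander_freq_hz: float = 0.3
    hum_amplitude: float = 0.02
    hum_freq_hz: float = 50.0
    ectopic_rate_per_minute: float = 0.0  # probability of an RR spike artifact
    sampling_rate: float = 100.0
    record_prefix: str = "synth"
    seed: int = 0


@dataclass
class SynthRecord:
    """One generated recording with its ground truth."""

    record: ECGRecord
    labels: MinuteLabels
    r_times: np.ndarray = field(repr=False)
    rr_ms: np.ndarray = field(repr=False)
    amplitude_factors: np.ndarray = field(repr=False)


def simulate_labels(config: SynthConfig, rng: np.random.Generator) -> MinuteLabels:
    """Alternating normal/apneic episodes with configured length distributions.

    Resamples (bounded retries) until the apneic-minute fraction lies inside
    ``apnea_fraction_bounds``, so every record is learnable but not trivial.
    """
    n = config.minutes_per_record
    if n < 1:
        raise ValueError("minutes_per_record must be >= 1")
    lo, hi = config.apnea_fraction_bounds
    for _ in range(200):
        labels: list[bool] = []
        apneic = False
        while len(labels) < n:
            span = config.apnea_episode_minutes if apneic else config.normal_episode_minutes
            length = int(rng.integers(span[0], span[1] + 1))
            labels.extend([apneic] * length)
            apneic = not apneic
        arr = np.array(labels[:n], dtype=bool)
        if lo <= arr.mean() <= hi:
            return MinuteLabels(record_id="synthetic", labels=arr)
    raise RuntimeError(
        "could not draw a label sequence inside the apneic-fraction bounds; "
        "episode length settings are inconsistent with the bounds"
    )


def _apnea_envelope(labels: np.ndarray, tau_s: float) -> np.ndarray:
    """First-order smoothed apnea indicator on a 1 Hz grid."""
    seconds = np.repeat(labels.astype(float), 60)
    if tau_s <= 0:
        return seconds
    env = np.empty_like(seconds)
    e = 0.0
    alpha = 1.0 / tau_s
    for k, ind in enumerate(seconds):
        e += (ind - e) * min(alpha, 1.0)
        env[k] = e
    return env


def simulate_rr(
    labels: MinuteLabels, config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ground-truth beat times, RR series (ms) and per-beat amplitude factors.

    The instantaneous RR is the baseline plus RSA (scaled by 1-envelope) plus
    the CVHR oscillation (scaled by the apnea envelope) plus white jitter,
    clipped to the physiological band; beat times accumulate from it.  During
    apnea the R amplitude is modulated at the CVHR rate with depth
    ``amp_modulation_depth``.
    """
    if labels.n_segments == 0:
        raise ValueError("labels must be non-empty")
    env_1hz = _apnea_envelope(labels.labels, config.transition_tau_s)
    t_end = labels.n_segments * 60.0
    baseline = config.baseline_rr_ms + config.baseline_rr_jitter_ms * rng.standard_normal()
    amp_phase = rng.uniform(0, 2 * np.pi)
    times: list[float] = []
    factors: list[float] = []
    t = float(rng.uniform(0.0, 0.5))
    while t < t_end:
        e = env_1hz[min(int(t), env_1hz.size - 1)]
        rr = (
            baseline
            + config.rsa_amplitude_ms * np.sin(2 * np.pi * config.rsa_freq_hz * t) * (1 - e)
            + config.cvhr_amplitude_ms * np.sin(2 * np.pi * config.cvhr_freq_hz * t) * e
            + config.rr_jitter_ms * rng.standard_normal()
        )
        if config.ectopic_rate_per_minute > 0 and rng.random() < (
            config.ectopic_rate_per_minute * rr / 60000.0
        ):
            rr *= rng.choice([0.4, 2.6])  # premature beat or dropped beat
        rr = float(np.clip(rr, *config.rr_clip_ms))
        times.append(t)
        factors.append(
            1.0
            + config.amp_modulation_depth
            * e
            * np.sin(2 * np.pi * config.cvhr_freq_hz * t + amp_phase)
        )
        t += rr / 1000.0
    times_arr = np.asarray(times)
    if times_arr.size < 2:
        raise ValueError("record too short to place beats")
    rr_ms = np.diff(times_arr) * 1000.0
    return times_arr, rr_ms, np.asarray(factors)


def render_ecg(
    r_times: np.ndarray,
    amplitude_factors: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
    n_minutes: int | None = None,
    record_id: str = "synthetic",
) -> ECGRecord:
    """Render a sampled ECG by placing a PQRST template at every beat time."""
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size < 2:
        raise ValueError("need at least 2 beats to render")
    fs = config.sampling_rate
    if n_minutes is None:
        n_minutes = int(np.ceil(r_times[-1] / 60.0))
    n = int(round(n_minutes * 60 * fs))
    x = np.zeros(n)
    # (offset s, relative amplitude, width s); R bump ~20 ms wide
    waves = (
        (-0.200, 0.12, 0.025),
        (-0.035, -0.12, 0.010),
        (0.000, 1.00, 0.009),
        (0.035, -0.15, 0.010),
        (0.250, 0.30, 0.040),
    )
    half_span = 0.45
    for t0, factor in zip(r_times, amplitude_factors):
        lo = max(int(np.ceil((t0 - half_span) * fs)), 0)
        hi = min(int(np.floor((t0 + half_span) * fs)) + 1, n)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) / fs - t0
        beat = np.zeros(hi - lo)
        for off, amp, width in waves:
            beat += amp * np.exp(-0.5 * ((tt - off) / width) ** 2)
        x[lo:hi] += config.ecg_amplitude_mv * factor * beat
    t = np.arange(n) / fs
    if config.wander_amplitude:
        x += config.wander_amplitude * np.sin(
            2 * np.pi * config.wander_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if config.hum_amplitude:
        x += config.hum_amplitude * np.sin(
            2 * np.pi * config.hum_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if config.noise_sd:
        x += config.noise_sd * rng.standard_normal(n)
    return ECGRecord(record_id=record_id, sampling_rate=fs, samples=x)


def generate_record(config: SynthConfig, index: int) -> SynthRecord:
    """One reproducible record; the per-record stream derives from (seed, index).

    A ``healthy_fraction`` share of records draws its episode pattern from the
    healthy settings (rare, short apneic runs, AHI < 5), so a generated cohort
    contains both SAS-positive and SAS-negative subjects, as a screening
    population does.
    """
    rng = np.random.default_rng([config.seed, index])
    record_id = f"{config.record_prefix}{index:03d}"
    if rng.random() < config.healthy_fraction:
        label_config = replace(
            config,
            normal_episode_minutes=config.healthy_normal_episode_minutes,
            apnea_episode_minutes=config.healthy_apnea_episode_minutes,
            apnea_fraction_bounds=config.healthy_apnea_fraction_bounds,
        )
    else:
        label_config = config
    labels = simulate_labels(label_config, rng)
    labels = MinuteLabels(record_id=record_id, labels=labels.labels)
    r_times, rr_ms, factors = simulate_rr(labels, config, rng)
    ecg = render_ecg(
        r_times, factors, config, rng,
        n_minutes=config.minutes_per_record, record_id=record_id,
    )
    return SynthRecord(
        record=ecg, labels=labels, r_times=r_times, rr_ms=rr_ms,
        amplitude_factors=factors,
    )


def generate_dataset(config: SynthConfig) -> list[SynthRecord]:
    if config.n_records < 1:
        raise ValueError("n_records must be >= 1")
    return [generate_record(config, i) for i in range(config.n_records)]


def write_dataset(
    records: list[SynthRecord], directory: str | Path, config: SynthConfig
) -> Path:
    """Serialize a dataset in the package's I/O dialects plus a manifest.

    Per record: WFDB 16-bit header/signal pair, plain-text annotations, and a
    ground-truth R-time file; ``manifest.json`` lists all config values.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        rid = rec.record.record_id
        write_wfdb_record(rec.record, directory)
        write_minute_annotations(rec.labels, directory / f"{rid}.ann", dialect="text")
        with open(directory / f"{rid}.rtimes.txt", "w") as fh:
            for t in rec.r_times:
                fh.write(f"{float(t)!r}\n")
        entries.append(
            {
                "record_id": rid,
                "signal": f"{rid}.hea",
                "annotations": f"{rid}.ann",
                "r_times": f"{rid}.rtimes.txt",
            }
        )
    manifest = {"config": asdict(config), "records": entries}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return directory / "manifest.json"
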
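import numpy as np
import pytest

from ecgscreen import SynthConfig, generate_record


@pytest.fixture(scope="session")
def clean_synth_config():
    """A short, noise-light recording for detector ground-truth checks."""
    return SynthConfig(
        n_records=1,
        minutes_per_record=5,
        noise_sd=0.01,
        wander_amplitude=0.05,
        hum_amplitude=0.01,
        seed=1,
    )


@pytest.fixture(scope="session")
def clean_record(clean_synth_config):
    return generate_record(clean_synth_config, 0)


def match_peaks(truth: np.ndarray, detected: np.ndarray, tol_s: float = 0.05):
    """Greedy one-to-one matching of detected peaks to ground truth.

    Returns (recall, precision, n_duplicates) where duplicates are detections
    within the tolerance of an already-matched truth peak.
    """
    truth = np.asarray(truth)
    detected = np.asarray(detected)
    used = np.zeros(truth.size, dtype=bool)
    matched = 0
    duplicates = 0
    for d in detected:
        i = int(np.argmin(np.abs(truth - d)))
        if abs(truth[i] - d) <= tol_s:
            if used[i]:
                duplicates += 1
            else:
                used[i] = True
                matched += 1
    recall = matched / truth.size if truth.size else 0.0
    precision = matched / detected.size if detected.size else 0.0
    return recall, precision, duplicates
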
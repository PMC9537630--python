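import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pwavekit.delineate import detect_qrs, locate_p_waves
from pwavekit.preprocess import preprocess
from pwavekit.synthetic_data import (BeatTemplateParams, simulate_ecg,
                                     white_sd_for_snr)

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

FS = 500.0


@pytest.fixture(scope="session")
def beat_params():
    return BeatTemplateParams(p_duration_mean=140.0, p_duration_sd=20.0)


@pytest.fixture(scope="session")
def clean_record(beat_params):
    """300 s clean record (~300 beats at 60 bpm) with exact fiducials."""
    return simulate_ecg(beat_params, 300.0, fs=FS, seed=7)


@pytest.fixture(scope="session")
def noisy_record(clean_record):
    """The clean record plus white noise at 20 dB SNR."""
    ecg, truth = clean_record
    rng = np.random.default_rng(3)
    sd = white_sd_for_snr(ecg, 20.0)
    return ecg.with_samples(ecg.samples + rng.normal(0, sd, ecg.n)), truth


def delineate_record(ecg):
    proc = preprocess(ecg)
    qrs = detect_qrs(proc)
    return qrs, locate_p_waves(proc, qrs)


@pytest.fixture(scope="session")
def delineated_clean(clean_record):
    return delineate_record(clean_record[0])


@pytest.fixture(scope="session")
def delineated_noisy(noisy_record):
    return delineate_record(noisy_record[0])


def match_to_truth(qrs, fids, truth, fs=FS, tol_ms=10.0):
    """Pair each delineated beat with the nearest true beat by R time."""
    pairs = []
    r_ms = qrs.r_peak_idx * 1000.0 / fs
    for f, r in zip(fids, r_ms):
        k = int(np.argmin(np.abs(truth.r_peak_ms - r)))
        if abs(truth.r_peak_ms[k] - r) <= tol_ms:
            pairs.append((f, k))
    return pairs
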
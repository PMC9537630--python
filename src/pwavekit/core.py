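"""Core container for single-lead ECG signals.

A record is a uniformly sampled voltage series in millivolts.  All modules
exchange :class:`EcgSignal` objects; times exported to disk are seconds
(sample index / sampling rate) and delineation results are integer sample
indices converted to milliseconds at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ArgumentError


@dataclass
class EcgSignal:
    """Uniformly sampled single-lead ECG voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage in millivolts.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time offset of the first sample, in seconds.
    label : str
        Free-text record label (patient id, lead name, ...).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ArgumentError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ArgumentError("an ECG record needs at least 2 samples")
        if not np.isfinite(self.samples).all():
            raise ArgumentError("samples must be finite")
        if not (self.fs > 0):
            raise ArgumentError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times_s(self) -> np.ndarray:
        """Sample times in seconds (t0 + index / fs)."""
        return self.t0 + np.arange(self.n) / self.fs

    def ms_to_samples(self, ms: float) -> int:
        """Round a duration in milliseconds to the nearest sample count."""
        return int(round(ms * self.fs / 1000.0))

    def samples_to_ms(self, idx: float) -> float:
        """Convert a sample index (or count) to milliseconds."""
        return float(idx) * 1000.0 / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgSignal":
        """Copy of this record with the voltage series replaced."""
        return replace(self, samples=np.asarray(samples, dtype=float))
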
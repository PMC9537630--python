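"""Plain-text I/O: ECG records, annotations, feature and cohort tables.

ECG records travel as two-column CSV (``time_s,amplitude_mV``), annotations
and tables as headed CSV.  Every writer accepts provenance comment lines
(``# key=value``) that readers skip; the pipeline uses them to embed the
configuration hash and seed in every output file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EcgSignal
from .delineate import PWaveFiducials
from .errors import FormatError

__all__ = [
    "read_ecg", "write_ecg",
    "read_annotations", "write_annotations",
    "read_table", "write_table",
]

ECG_COLUMNS = ("time_s", "amplitude_mV")
ANN_COLUMNS = ("beat_index", "onset_ms", "peak_ms", "offset_ms", "valid")
# Relative tolerance on sampling-interval jitter when inferring fs.
_JITTER_PPM = 1.0


def _write_comments(fh, comments: Sequence[str] | None) -> None:
    for line in comments or ():
        fh.write(f"# {line}\n")


def write_ecg(sig: EcgSignal, path: str | Path,
              comments: Sequence[str] | None = None) -> None:
    """Write a record as ``time_s,amplitude_mV`` CSV."""
    path = Path(path)
    t = sig.times_s()
    with open(path, "w") as fh:
        _write_comments(fh, comments)
        fh.write(",".join(ECG_COLUMNS) + "\n")
        for ti, vi in zip(t, sig.samples):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def read_ecg(path: str | Path, label: str = "") -> EcgSignal:
    """Read a two-column ECG CSV; the sampling rate is inferred from times.

    Raises :class:`FormatError` on a missing/misnamed header or when the
    sampling interval jitters by more than 1 ppm (non-uniform sampling).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in ECG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{','.join(ECG_COLUMNS)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if dt.min() <= 0:
        raise FormatError(f"{path}: time column must be strictly increasing")
    if (dt.max() - dt.min()) / dt.mean() > _JITTER_PPM * 1e-6:
        raise FormatError(f"{path}: non-uniform sampling beyond 1 ppm jitter")
    fs = 1.0 / dt.mean()
    return EcgSignal(df["amplitude_mV"].to_numpy(dtype=float), fs=fs,
                     t0=float(t[0]), label=label or path.stem)


def write_annotations(fiducials: Sequence[PWaveFiducials], fs: float,
                      path: str | Path,
                      comments: Sequence[str] | None = None) -> None:
    """Write per-beat fiducials as CSV in milliseconds from record start."""
    ms = 1000.0 / fs
    with open(Path(path), "w") as fh:
        _write_comments(fh, comments)
        fh.write(",".join(ANN_COLUMNS) + "\n")
        for f in fiducials:
            fh.write(f"{f.beat_index},{f.onset_idx * ms:.3f},"
                     f"{f.peak_idx * ms:.3f},{f.offset_idx * ms:.3f},"
                     f"{int(f.valid)}\n")


def read_annotations(path: str | Path, fs: float) -> list[PWaveFiducials]:
    """Read a fiducial CSV back into :class:`PWaveFiducials` (sample units)."""
    df = pd.read_csv(Path(path), comment="#")
    missing = [c for c in ANN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(PWaveFiducials(
            beat_index=int(row.beat_index),
            onset_idx=int(round(row.onset_ms * fs / 1000.0)),
            peak_idx=int(round(row.peak_ms * fs / 1000.0)),
            offset_idx=int(round(row.offset_ms * fs / 1000.0)),
            isoelectric_mv=0.0, amplitude_mv=np.nan, valid=bool(row.valid)))
    return out


def write_table(df: pd.DataFrame, path: str | Path,
                comments: Sequence[str] | None = None) -> None:
    """Write any tabular artifact as CSV with optional provenance comments."""
    with open(Path(path), "w") as fh:
        _write_comments(fh, comments)
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV table written by :func:`write_table`."""
    try:
        return pd.read_csv(Path(path), comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
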
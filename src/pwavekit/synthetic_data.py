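"""Synthetic single-lead ECG and clinical cohort generation.

The study this package operationalises compared patients who developed
postoperative atrial fibrillation (POAF) after cardiac surgery with patients
who did not, using (a) long-term single-lead ECG recorded before surgery and
(b) a table of clinical covariates.  No recording is publicly deposited, so
every downstream stage is exercised against synthetic data with known ground
truth:

* :func:`simulate_ecg` renders a beat train from smooth raised-cosine lobes
  (P, QRS, T) with per-beat P-wave duration drawn from a patient-specific
  truncated normal distribution, plus configurable baseline wander, powerline
  and white noise.  Exact fiducials are returned as :class:`SimTruth`.
* :func:`simulate_cohort` draws a two-group clinical covariate table whose
  per-group means/SDs/proportions reproduce the published cohort structure
  (the POAF group is older, has larger left atria, lower GFR, longer
  ventilation, and wider / more variable P waves).

All randomness flows through a single ``numpy`` Generator seeded by the
caller; identical (parameters, seed) give bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import EcgSignal
from .errors import ArgumentError, BeatOverlapWarning, ConfigError

__all__ = [
    "BeatTemplateParams",
    "NoiseSpec",
    "SimTruth",
    "CohortSpec",
    "ContinuousVar",
    "BinaryVar",
    "SkewedVar",
    "DerivedVar",
    "simulate_ecg",
    "simulate_cohort",
    "simulate_patient_beat_params",
    "default_cohort_spec",
    "white_sd_for_snr",
    "P_DURATION_FLOOR_MS",
]

# Fixed morphology constants (mV); only the P wave carries tunable amplitude
# because only P-wave geometry is measured downstream.
QRS_AMPLITUDE_MV = 1.0
T_AMPLITUDE_MV = 0.25
ST_SEGMENT_MS = 100.0
# Minimum isoelectric PR segment between P offset and QRS onset; keeps the
# baseline estimate downstream well defined even for very wide P waves.
MIN_PR_SEGMENT_MS = 50.0
# Truncation floor for simulated P durations: prevents degenerate zero-width
# waves when the per-patient SD is large.
P_DURATION_FLOOR_MS = 40.0


@dataclass
class BeatTemplateParams:
    """Parametric description of one patient's beat morphology.

    All durations in milliseconds, amplitudes in millivolts.  ``pr_interval``
    is measured from P onset to QRS onset; when a drawn P duration would not
    leave ``MIN_PR_SEGMENT_MS`` of flat baseline before the QRS, the P wave of
    that beat is shifted earlier so the PR segment is preserved.
    """

    p_duration_mean: float = 120.0
    p_duration_sd: float = 10.0
    p_amplitude: float = 0.2
    p_peak_fraction: float = 0.5
    pr_interval: float = 180.0
    qrs_duration: float = 90.0
    t_duration: float = 200.0
    rr_mean: float = 1000.0
    rr_sd: float = 40.0

    def __post_init__(self) -> None:
        for name in ("p_duration_mean", "pr_interval", "qrs_duration",
                     "t_duration", "rr_mean"):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be positive")
        if self.p_duration_sd < 0 or self.rr_sd < 0:
            raise ArgumentError("standard deviations must be non-negative")
        if not (0.0 < self.p_peak_fraction < 1.0):
            raise ArgumentError("p_peak_fraction must lie in (0, 1)")
        if self.p_amplitude < 0:
            raise ArgumentError("p_amplitude must be non-negative")


@dataclass
class NoiseSpec:
    """Additive noise model: baseline wander + powerline + white noise.

    Amplitudes in mV (sinusoid peak amplitude for the narrowband terms,
    standard deviation for the white term); any may be zero.
    """

    baseline_wander_mv: float = 0.0
    baseline_wander_hz: float = 0.3
    powerline_mv: float = 0.0
    powerline_hz: float = 50.0
    white_sd_mv: float = 0.0

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls()

    def render(self, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
        t = np.arange(n) / fs
        out = np.zeros(n)
        if self.baseline_wander_mv:
            phase = rng.uniform(0, 2 * np.pi)
            out += self.baseline_wander_mv * np.sin(
                2 * np.pi * self.baseline_wander_hz * t + phase)
        if self.powerline_mv:
            phase = rng.uniform(0, 2 * np.pi)
            out += self.powerline_mv * np.sin(
                2 * np.pi * self.powerline_hz * t + phase)
        if self.white_sd_mv:
            out += rng.normal(0.0, self.white_sd_mv, size=n)
        return out


@dataclass
class SimTruth:
    """Exact per-beat fiducials of a simulated record (ms from record start)."""

    onset_ms: np.ndarray
    peak_ms: np.ndarray
    offset_ms: np.ndarray
    r_peak_ms: np.ndarray
    p_duration_mean_ms: float
    p_duration_sd_ms: float

    def __post_init__(self) -> None:
        for name in ("onset_ms", "peak_ms", "offset_ms", "r_peak_ms"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (np.all(self.onset_ms < self.peak_ms)
                and np.all(self.peak_ms < self.offset_ms)):
            raise ArgumentError("fiducials must satisfy onset < peak < offset")
        if self.onset_ms.size > 1 and not np.all(np.diff(self.onset_ms) > 0):
            raise ArgumentError("beats must be strictly ordered in time")

    @property
    def n_beats(self) -> int:
        return int(self.onset_ms.size)

    @property
    def durations_ms(self) -> np.ndarray:
        return self.offset_ms - self.onset_ms

    @property
    def peak_times_ms(self) -> np.ndarray:
        """Onset-to-peak intervals per beat."""
        return self.peak_ms - self.onset_ms


def _add_lobe(sig: np.ndarray, fs: float, start_ms: float, peak_ms: float,
              end_ms: float, amp: float) -> None:
    """Add a raised-cosine lobe (sin^2 rise and fall, apex at ``peak_ms``).

    The lobe leaves and rejoins the baseline with zero slope, so its feet
    intersect the isoelectric line tangentially — the geometry the
    delineator's measurement rule assumes.
    """
    i0 = int(math.ceil(start_ms * fs / 1000.0))
    i1 = int(math.floor(end_ms * fs / 1000.0))
    if i1 <= i0:
        return
    idx = np.arange(max(i0, 0), min(i1 + 1, sig.size))
    if idx.size == 0:
        return
    t = idx * 1000.0 / fs
    rise = t <= peak_ms
    u = np.empty_like(t)
    u[rise] = (t[rise] - start_ms) / max(peak_ms - start_ms, 1e-9)
    u[~rise] = 1.0 - (t[~rise] - peak_ms) / max(end_ms - peak_ms, 1e-9)
    sig[idx] += amp * np.sin(0.5 * np.pi * np.clip(u, 0.0, 1.0)) ** 2


def _draw_p_durations(n: int, mean: float, sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    """P durations ~ Normal(mean, sd) truncated at ``P_DURATION_FLOOR_MS``."""
    if sd == 0:
        return np.full(n, max(mean, P_DURATION_FLOOR_MS))
    a = (P_DURATION_FLOOR_MS - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                               random_state=rng)


def simulate_ecg(params: BeatTemplateParams, duration_s: float, fs: float = 500.0,
                 noise: NoiseSpec | None = None, seed: int = 0,
                 ) -> tuple[EcgSignal, SimTruth]:
    """Render a synthetic single-lead ECG with exact P-wave ground truth.

    Beats are anchored at R-peak times produced by a Gaussian RR-interval
    random walk; each beat is the sum of three raised-cosine lobes (P, QRS, T)
    on a zero baseline, and noise is added afterwards per ``noise``.

    Returns the signal together with a :class:`SimTruth` holding the exact
    onset / first-peak / offset time of every rendered P wave.
    """
    if duration_s <= 0:
        raise ArgumentError("duration must be positive")
    if fs < 250:
        raise ArgumentError("sampling rate below 250 Hz cannot resolve "
                            "millisecond-scale P-wave geometry")
    noise = noise or NoiseSpec.none()
    rng = np.random.default_rng(seed)

    total_ms = duration_s * 1000.0
    # First R peak leaves room for the widest plausible P wave.
    r_times = []
    t = max(params.rr_mean * 0.6,
            params.pr_interval + params.qrs_duration / 2 + 300.0)
    tail = params.qrs_duration / 2 + ST_SEGMENT_MS + params.t_duration
    while t + tail < total_ms:
        r_times.append(t)
        rr = params.rr_mean if params.rr_sd == 0 else rng.normal(
            params.rr_mean, params.rr_sd)
        t += max(rr, 300.0)  # physiologic refractory floor
    r_times = np.asarray(r_times)
    if r_times.size == 0:
        raise ArgumentError("record too short to hold a single beat")

    d = _draw_p_durations(r_times.size, params.p_duration_mean,
                          params.p_duration_sd, rng)
    qrs_on = r_times - params.qrs_duration / 2
    pr_eff = np.maximum(params.pr_interval, d + MIN_PR_SEGMENT_MS)
    p_on = qrs_on - pr_eff
    p_off = p_on + d
    p_peak = p_on + params.p_peak_fraction * d

    n = int(round(duration_s * fs))
    sig = np.zeros(n)
    prev_t_end = -np.inf
    overlapped = False
    for k in range(r_times.size):
        if p_on[k] < prev_t_end:
            overlapped = True
        _add_lobe(sig, fs, p_on[k], p_peak[k], p_off[k], params.p_amplitude)
        _add_lobe(sig, fs, qrs_on[k], r_times[k],
                  qrs_on[k] + params.qrs_duration, QRS_AMPLITUDE_MV)
        t_start = qrs_on[k] + params.qrs_duration + ST_SEGMENT_MS
        t_end = t_start + params.t_duration
        _add_lobe(sig, fs, t_start, (t_start + t_end) / 2, t_end,
                  T_AMPLITUDE_MV)
        prev_t_end = t_end
    if overlapped:
        warnings.warn("beat template wider than RR interval: overlapping "
                      "lobes were summed", BeatOverlapWarning, stacklevel=2)

    sig += noise.render(n, fs, rng)
    ecg = EcgSignal(sig, fs=fs, label=f"synthetic seed={seed}")
    truth = SimTruth(onset_ms=p_on, peak_ms=p_peak, offset_ms=p_off,
                     r_peak_ms=r_times,
                     p_duration_mean_ms=params.p_duration_mean,
                     p_duration_sd_ms=params.p_duration_sd)
    return ecg, truth


def white_sd_for_snr(clean: EcgSignal, snr_db: float) -> float:
    """White-noise SD (mV) giving the requested SNR against a clean record."""
    rms = float(np.sqrt(np.mean(clean.samples ** 2)))
    return rms / (10.0 ** (snr_db / 20.0))


# --------------------------------------------------------------------------
# Patient-level P-wave distributions per outcome group.
#
# Per-patient mean beat-to-beat P duration and its SD are themselves drawn
# from group-level distributions matching the published feature table: the
# POAF group has a wider mean P wave (141 vs 133 ms) and more beat-to-beat
# variability (SD 19 vs 15 ms), with substantial between-patient spread.
P_MEAN_BY_GROUP = {0: (133.0, 23.0), 1: (141.0, 25.0)}
P_SD_BY_GROUP = {0: (15.0, 7.0), 1: (19.0, 11.0)}


def simulate_patient_beat_params(group: int, rng: np.random.Generator,
                                 base: BeatTemplateParams | None = None,
                                 ) -> BeatTemplateParams:
    """Draw one patient's beat-template parameters given the outcome group.

    Only the P-duration distribution differs between groups; the remaining
    morphology comes from ``base`` (package defaults if omitted).
    """
    if group not in (0, 1):
        raise ArgumentError("group must be 0 (no POAF) or 1 (POAF)")
    base = base or BeatTemplateParams()
    m_mu, m_sd = P_MEAN_BY_GROUP[group]
    s_mu, s_sd = P_SD_BY_GROUP[group]
    p_mean = max(float(rng.normal(m_mu, m_sd)), 60.0)
    p_sd = max(float(rng.normal(s_mu, s_sd)), 2.0)
    return BeatTemplateParams(
        p_duration_mean=p_mean, p_duration_sd=p_sd,
        p_amplitude=base.p_amplitude, p_peak_fraction=base.p_peak_fraction,
        pr_interval=base.pr_interval, qrs_duration=base.qrs_duration,
        t_duration=base.t_duration, rr_mean=base.rr_mean, rr_sd=base.rr_sd)


# --------------------------------------------------------------------------
# Clinical cohort


@dataclass
class ContinuousVar:
    """Normal per group: (mean_group0, mean_group1), (sd0, sd1)."""
    mean: tuple[float, float]
    sd: tuple[float, float]


@dataclass
class BinaryVar:
    """Bernoulli per group: (p0, p1)."""
    p: tuple[float, float]


@dataclass
class SkewedVar:
    """Right-skewed positive variable, lognormal matched to the per-group
    median and interquartile range."""
    median: tuple[float, float]
    iqr: tuple[tuple[float, float], tuple[float, float]]  # (q1, q3) per group


@dataclass
class DerivedVar:
    """Deterministic function of previously drawn columns."""
    func: Callable[[pd.DataFrame], pd.Series]


@dataclass
class CohortSpec:
    """Two-group cohort: group sizes plus one distribution spec per variable."""

    n_group0: int
    n_group1: int
    variables: Mapping[str, object]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group0 < 1 or self.n_group1 < 1:
            raise ArgumentError("each group needs at least one patient")
        for name, var in self.variables.items():
            if isinstance(var, ContinuousVar):
                if min(var.sd) < 0:
                    raise ArgumentError(f"{name}: SD must be non-negative")
            elif isinstance(var, BinaryVar):
                if not all(0.0 <= p <= 1.0 for p in var.p):
                    raise ArgumentError(f"{name}: proportions must be in [0,1]")
            elif isinstance(var, (SkewedVar, DerivedVar)):
                pass
            else:
                raise ConfigError(f"unknown variable kind for '{name}': "
                                  f"{type(var).__name__}")


def _draw_skewed(median: float, q1: float, q3: float, size: int,
                 rng: np.random.Generator) -> np.ndarray:
    # Lognormal with the requested median; sigma from the IQR ratio
    # (z_{.75} - z_{.25} = 1.349).
    mu = math.log(median)
    sigma = math.log(q3 / q1) / 1.349 if q3 > q1 else 0.0
    return np.exp(rng.normal(mu, sigma, size=size))


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a two-group clinical table; one row per patient.

    Continuous variables are Normal(mean, SD) per group, skewed variables
    lognormal matched to median/IQR, binary variables Bernoulli, derived
    variables computed last.  Columns: ``patient_id``, ``poaf`` (group label),
    then the spec's variables in order.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_group0, spec.n_group1
    group = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    df = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n0 + n1)],
        "poaf": group,
    })
    derived: list[tuple[str, DerivedVar]] = []
    for name, var in spec.variables.items():
        if isinstance(var, DerivedVar):
            derived.append((name, var))
            continue
        col = np.empty(n0 + n1)
        for g, sl in ((0, slice(0, n0)), (1, slice(n0, n0 + n1))):
            size = n0 if g == 0 else n1
            if isinstance(var, ContinuousVar):
                if var.sd[g] == 0:
                    col[sl] = var.mean[g]
                else:
                    col[sl] = rng.normal(var.mean[g], var.sd[g], size=size)
            elif isinstance(var, BinaryVar):
                col[sl] = (rng.random(size) < var.p[g]).astype(float)
            elif isinstance(var, SkewedVar):
                q1, q3 = var.iqr[g]
                col[sl] = _draw_skewed(var.median[g], q1, q3, size, rng)
        df[name] = col
    for name, var in derived:
        df[name] = var.func(df)
    return df


def default_cohort_spec(n_group0: int = 69, n_group1: int = 31,
                        seed: int = 0, include_p_features: bool = True,
                        ) -> CohortSpec:
    """Cohort spec reproducing the published two-group covariate structure.

    Group 0 is the no-POAF group (n = 69 in the study), group 1 the POAF
    group (n = 31).  Continuous variables carry the published mean ± SD per
    group, operative-time variables the published median (IQR), binary
    variables the published proportions.  When ``include_p_features`` is set,
    patient-level P-wave summary features are drawn as well: Pmax, PWd and
    the five remaining parameters, with Pmin derived as Pmax − PWd so the
    dispersion identity holds row-wise by construction.

    Variables are drawn independently within group; the published table gives
    no joint structure to copy.
    """
    v: dict[str, object] = {
        "sex": BinaryVar((0.623, 0.516)),           # male = 1
        "age": ContinuousVar((50.43, 55.97), (10.59, 8.49)),
        "height": ContinuousVar((163.44, 162.42), (8.0, 8.5)),
        "weight": ContinuousVar((64.28, 63.42), (10.41, 9.0)),
        "bmi": ContinuousVar((23.96, 23.99), (2.65, 2.44)),
        "dm": BinaryVar((0.043, 0.0)),
        "chd": BinaryVar((0.072, 0.161)),
        "renal_failure": BinaryVar((0.029, 0.0)),
        "hypertension": BinaryVar((0.232, 0.355)),
        "stroke": BinaryVar((0.0, 0.032)),
        "hyperlipidemia": BinaryVar((0.029, 0.097)),
        "beta_blocker": BinaryVar((0.159, 0.29)),
        "ccb": BinaryVar((0.174, 0.097)),
        "statin": BinaryVar((0.058, 0.097)),
        "anticoagulant": BinaryVar((0.043, 0.097)),
        "digoxin": BinaryVar((0.058, 0.016)),
        "acei_arb": BinaryVar((0.174, 0.129)),
        "diuretics": BinaryVar((0.551, 0.645)),
        "la": ContinuousVar((40.06, 46.0), (7.63, 11.94)),
        "ra": ContinuousVar((35.32, 37.48), (5.54, 11.15)),
        "lvef": ContinuousVar((62.57, 59.97), (9.35, 12.45)),
        "creatinine": ContinuousVar((76.59, 81.87), (15.12, 12.89)),
        "gfr": ContinuousVar((93.00, 82.02), (13.81, 14.94)),
        "urea": ContinuousVar((5.59, 6.40), (1.32, 1.75)),
        "alt": ContinuousVar((21.64, 21.23), (16.16, 9.87)),
        "ast": ContinuousVar((20.90, 22.00), (9.10, 5.25)),
        "alp": ContinuousVar((78.91, 83.42), (34.31, 30.71)),
        "tg": ContinuousVar((1.47, 1.55), (1.01, 1.04)),
        "cho": ContinuousVar((4.58, 4.39), (1.04, 0.82)),
        "surgery_time": SkewedVar((4.0, 4.0), ((3.0, 4.5), (3.0, 4.5))),
        "cpb": SkewedVar((110.0, 110.0), ((85.0, 133.5), (96.0, 137.0))),
        "acc": SkewedVar((73.0, 78.0), ((60.0, 103.5), (59.0, 108.0))),
        "mech_vent": SkewedVar((33.0, 52.0), ((18.5, 47.0), (34.0, 88.0))),
        "single_valve": BinaryVar((0.493, 0.226)),
        "multiple_valve": BinaryVar((0.217, 0.549)),
        "cabg": BinaryVar((0.058, 0.097)),
        "aortic_replacement": BinaryVar((0.246, 0.129)),
    }
    if include_p_features:
        v.update({
            "pmax": ContinuousVar((167.0, 184.0), (31.0, 37.0)),
            "pwd": ContinuousVar((62.0, 80.0), (28.0, 35.0)),
            "pmin": DerivedVar(lambda df: df["pmax"] - df["pwd"]),
            "pmean": ContinuousVar((133.0, 141.0), (23.0, 25.0)),
            "pstd": ContinuousVar((15.0, 19.0), (7.0, 11.0)),
            "pptmean": ContinuousVar((72.0, 73.0), (16.0, 18.0)),
            "pptstd": ContinuousVar((13.0, 14.0), (6.0, 8.0)),
        })
    return CohortSpec(n_group0=n_group0, n_group1=n_group1, variables=v,
                      seed=seed)
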
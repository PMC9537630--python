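"""QRS detection and P-wave delineation against simulated ground truth."""

import numpy as np
import pytest

from conftest import FS, delineate_record, match_to_truth
from pwavekit.core import EcgSignal
from pwavekit.delineate import (PWaveFiducials, detect_qrs, locate_p_waves,
                                qc_filter)
from pwavekit.errors import ArgumentError, FlatSignalWarning
from pwavekit.preprocess import preprocess
from pwavekit.synthetic_data import BeatTemplateParams, simulate_ecg


class TestDetectQrs:
    def test_clean_record_every_beat_found_within_10_ms(self, clean_record,
                                                        delineated_clean):
        _, truth = clean_record
        qrs, _ = delineated_clean
        assert qrs.n_beats == truth.n_beats
        r_ms = qrs.r_peak_idx * 1000.0 / FS
        assert np.all(np.abs(r_ms - truth.r_peak_ms) <= 10.0)

    def test_flat_signal_yields_zero_beats_with_warning(self):
        sig = EcgSignal(np.zeros(5000), fs=FS)
        with pytest.warns(FlatSignalWarning):
            qrs = detect_qrs(sig)
        assert qrs.n_beats == 0

    def test_snr20_detection_sensitivity_at_least_99pct(self, noisy_record,
                                                        delineated_noisy):
        _, truth = noisy_record
        qrs, _ = delineated_noisy
        r_ms = qrs.r_peak_idx * 1000.0 / FS
        hits = sum(np.min(np.abs(r_ms - t)) <= 10.0 for t in truth.r_peak_ms)
        assert hits / truth.n_beats >= 0.99

    def test_refractory_period_enforced(self, delineated_clean):
        qrs, _ = delineated_clean
        assert np.all(np.diff(qrs.r_peak_idx) >= 0.2 * FS)
        assert np.all(qrs.qrs_onset_idx <= qrs.r_peak_idx)


class TestLocatePWaves:
    def test_clean_edges_within_one_sample(self, clean_record,
                                           delineated_clean):
        _, truth = clean_record
        qrs, fids = delineated_clean
        pairs = match_to_truth(qrs, fids, truth)
        assert len(pairs) >= 0.95 * truth.n_beats
        on_err, off_err = [], []
        for f, k in pairs:
            if not f.valid:
                continue
            on_err.append(f.onset_idx * 1000.0 / FS - truth.onset_ms[k])
            off_err.append(f.offset_idx * 1000.0 / FS - truth.offset_ms[k])
        # ±1 sample (±2 ms at 500 Hz) for the large majority of clean beats
        assert np.quantile(np.abs(on_err), 0.95) <= 2.0
        assert np.quantile(np.abs(off_err), 0.95) <= 2.0

    def test_zero_amplitude_p_wave_marked_invalid(self):
        params = BeatTemplateParams(p_amplitude=0.0)
        ecg, _ = simulate_ecg(params, 30.0, seed=2)
        _, fids = delineate_record(ecg)
        assert len(fids) > 0
        assert not any(f.valid for f in fids)

    def test_fiducial_ordering_on_every_valid_beat(self, delineated_clean,
                                                   delineated_noisy):
        for _, fids in (delineated_clean, delineated_noisy):
            for f in fids:
                if f.valid:
                    assert f.onset_idx < f.peak_idx < f.offset_idx

    def test_negative_polarity_record_delineated(self):
        params = BeatTemplateParams(p_amplitude=0.2)
        ecg, truth = simulate_ecg(params, 60.0, seed=6)
        flipped = ecg.with_samples(-ecg.samples)
        qrs, fids = delineate_record(flipped)
        pairs = match_to_truth(qrs, fids, truth)
        errs = [f.duration_ms(FS) - truth.durations_ms[k]
                for f, k in pairs if f.valid]
        assert len(errs) > 0.9 * truth.n_beats
        assert np.mean(np.abs(errs)) <= 4.0

    def test_empty_qrs_annotation_rejected(self):
        sig = EcgSignal(np.zeros(5000), fs=FS)
        with pytest.warns(FlatSignalWarning):
            qrs = detect_qrs(sig)
        with pytest.raises(ArgumentError):
            locate_p_waves(sig, qrs)

    def test_error_monotone_in_noise_level(self, clean_record):
        """Mean absolute duration error does not improve as noise grows."""
        ecg, truth = clean_record
        maes = []
        for sd in (0.0, 0.02, 0.05):
            rng = np.random.default_rng(11)
            sig = ecg.with_samples(
                ecg.samples + (rng.normal(0, sd, ecg.n) if sd else 0.0))
            qrs, fids = delineate_record(sig)
            errs = [f.duration_ms(FS) - truth.durations_ms[k]
                    for f, k in match_to_truth(qrs, fids, truth) if f.valid]
            maes.append(np.mean(np.abs(errs)))
        assert maes[0] <= maes[1] <= maes[2]


def _beat(i, onset, peak, offset, amp=0.2, valid=True):
    return PWaveFiducials(i, onset, peak, offset, 0.0, amp, valid)


class TestQcFilter:
    def test_all_valid_passes_through(self):
        fids = [_beat(i, 100 * i, 100 * i + 30, 100 * i + 60)
                for i in range(10)]
        kept, report = qc_filter(fids, FS)
        assert kept == fids
        assert not report.excluded and report.valid_fraction == 1.0

    def test_out_of_range_duration_dropped(self):
        good = [_beat(i, 100 * i, 100 * i + 30, 100 * i + 60)
                for i in range(9)]
        bad = _beat(99, 5000, 5100, 5000 + int(0.5 * FS))  # 500 ms
        kept, _ = qc_filter(good + [bad], FS)
        assert bad not in kept and len(kept) == 9

    def test_low_amplitude_dropped(self):
        fids = [_beat(0, 0, 30, 60, amp=0.01),
                _beat(1, 100, 130, 160, amp=0.2)]
        kept, _ = qc_filter(fids, FS)
        assert len(kept) == 1 and kept[0].beat_index == 1

    def test_patient_flagged_when_valid_fraction_below_half(self):
        fids = ([_beat(i, 100 * i, 100 * i + 30, 100 * i + 60)
                 for i in range(4)]
                + [_beat(10 + i, -1, -1, -1, valid=False) for i in range(6)])
        _, report = qc_filter(fids, FS)
        assert report.excluded and report.valid_fraction == pytest.approx(0.4)

    def test_noise_corrupted_record_excluded(self):
        """A record mostly drowned in noise fails patient-level QC."""
        params = BeatTemplateParams()
        ecg, _ = simulate_ecg(params, 60.0, seed=13)
        rng = np.random.default_rng(13)
        loud = ecg.with_samples(ecg.samples + rng.normal(0, 0.25, ecg.n))
        qrs, fids = delineate_record(loud)
        _, report = qc_filter(fids, FS)
        assert report.excluded
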
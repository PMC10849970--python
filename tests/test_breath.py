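"""Breath segmentation, phase mapping, sigh and gasp detection."""

import numpy as np
import pandas as pd
import pytest

from respdyn import breath as B
from respdyn import synthetic as syn


def brute_force_sigh_flags(auc, window=51, factor=7.0, floor=1e-9):
    """Direct evaluation of the rolling-MAD outlier rule."""
    n = len(auc)
    flags = np.zeros(n, bool)
    half = window // 2
    for i in range(n):
        w = auc[max(0, i - half): min(n, i + half + 1)]
        med = np.median(w)
        mad = np.median(np.abs(w - np.median(w)))
        flags[i] = (auc[i] - med) > factor * max(mad, floor)
    return flags


def brute_force_gasp_epochs(ibi, window=7, start=1.0, stop=0.85):
    """Direct evaluation of the median-filter hysteresis rule."""
    n = len(ibi)
    half = window // 2
    sm = np.array(
        [np.median(ibi[max(0, i - half): min(n, i + half + 1)]) for i in range(n)]
    )
    epochs, in_ep, s = [], False, 0
    for i, v in enumerate(sm):
        if not in_ep and v > start:
            in_ep, s = True, i
        elif in_ep and v < stop:
            epochs.append((s, i - 1))
            in_ep = False
    if in_ep:
        epochs.append((s, n - 1))
    return epochs


def breaths_from_arrays(onsets, offsets, aucs=None):
    onsets, offsets = np.asarray(onsets, float), np.asarray(offsets, float)
    return pd.DataFrame(
        {
            "onset": onsets,
            "offset": offsets,
            "auc": aucs if aucs is not None else offsets - onsets,
            "ibi": np.append(np.diff(onsets), np.nan),
        }
    )


class TestIntegrateEMG:
    def test_out_of_band_sine_is_rejected(self, rng):
        # small in-band bursts riding on a 3x larger 100-Hz sine: the
        # envelope must track the bursts, not the out-of-band carrier
        rate = 20_000.0
        t = np.arange(int(2 * rate)) / rate
        gate = ((t % 0.5) < 0.2).astype(float)
        raw = (np.sin(2 * np.pi * 100 * t)
               + 0.3 * gate * np.sin(2 * np.pi * 1000 * t)
               + 0.005 * rng.normal(size=len(t)))
        env = B.integrate_emg(raw, rate).samples
        burst = env[gate[:: int(rate / 1000)][: len(env)] > 0.5]
        quiet = env[gate[:: int(rate / 1000)][: len(env)] < 0.5]
        assert np.median(burst) > 5 * np.median(quiet)

    def test_white_noise_output_has_unit_sd(self, rng):
        env = B.integrate_emg(rng.normal(size=40_000), 20_000.0)
        assert abs(env.samples.std() - 1.0) < 1e-9

    def test_burst_count_is_preserved(self, rng):
        # five 1-kHz carrier bursts -> five envelope bumps
        rate = 20_000.0
        t = np.arange(int(3 * rate)) / rate
        carrier = np.sin(2 * np.pi * 1000 * t)
        gate = np.zeros_like(t)
        for k in range(5):
            gate[(t > 0.5 * k + 0.2) & (t < 0.5 * k + 0.4)] = 1.0
        env = B.integrate_emg(carrier * gate + 0.02 * rng.normal(size=len(t)), rate)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(env.samples, height=0.5 * env.samples.max(),
                              distance=300)
        assert len(peaks) == 5

    def test_low_rate_is_rejected(self):
        with pytest.raises(ValueError, match="10 kHz"):
            B.integrate_emg(np.zeros(1000), 1000.0)


class TestDetectBreaths:
    def test_flat_trace_gives_empty_table(self):
        table = B.detect_breaths(B.DiaphragmTrace(np.zeros(5000), 1000.0))
        assert len(table) == 0

    def test_synthetic_eupnea_onsets_within_10ms(self, eupnea_small):
        trace = B.DiaphragmTrace(eupnea_small.diaphragm, 1000.0)
        table = B.detect_breaths(trace)
        true_on = eupnea_small.breaths_true.onset.values[1:-1]
        hits = [np.min(np.abs(table.onset.values - t)) for t in true_on]
        assert np.mean(np.asarray(hits) <= 0.010) >= 0.99

    def test_merged_bursts_yield_one_breath(self):
        t = np.arange(4000) / 1000.0
        x = np.exp(-((t - 1.0) ** 2) / 0.002) + np.exp(-((t - 1.05) ** 2) / 0.002)
        x = x / x.std()
        table = B.detect_breaths(B.DiaphragmTrace(x, 1000.0), min_distance_s=0.2)
        assert len(table) == 1

    def test_invariants(self, eupnea_small):
        table = B.detect_breaths(B.DiaphragmTrace(eupnea_small.diaphragm, 1000.0))
        on, off = table.onset.values, table.offset.values
        assert np.all(np.diff(on) > 0)
        assert np.all(off > on)
        assert np.all(off[:-1] < on[1:])
        assert np.allclose(table.ibi.values[:-1], np.diff(on))


class TestPhase:
    def test_inspiration_and_expiration_midpoints_exact(self):
        br = breaths_from_arrays([0.0, 1.0], [0.5, 1.5])
        phase = B.compute_phase(br, 1000.0, 2.0)
        assert phase.phi[250] == pytest.approx(np.pi / 2, abs=1e-12)
        assert phase.phi[750] == pytest.approx(-np.pi / 2, abs=1e-12)

    def test_offset_sample_is_pi_and_next_is_minus_pi(self):
        br = breaths_from_arrays([0.0, 1.0], [0.5, 1.5])
        phase = B.compute_phase(br, 1000.0, 2.0)
        assert phase.phi[500] == pytest.approx(np.pi, abs=1e-12)
        # the following sample wraps to -pi (exact up to one sample of slope)
        slope = np.pi / 500
        assert -np.pi <= phase.phi[501] <= -np.pi + slope + 1e-12

    def test_round_trip_recovers_breath_table(self):
        onsets = np.array([0.2, 1.1, 2.3, 3.0])
        offsets = np.array([0.6, 1.5, 2.65, 3.4])
        phase = B.compute_phase(breaths_from_arrays(onsets, offsets), 1000.0, 4.0)
        rec_on = np.flatnonzero(phase.phi == 0.0) / 1000.0
        rec_off = np.flatnonzero(phase.phi == np.pi) / 1000.0
        assert np.allclose(rec_on, onsets[:-1], atol=1e-9)
        assert np.allclose(rec_off, offsets[:-1], atol=1e-9)

    def test_samples_outside_breaths_are_invalid(self):
        phase = B.compute_phase(
            breaths_from_arrays([0.5, 1.5], [1.0, 1.9]), 1000.0, 2.5
        )
        assert np.all(np.isnan(phase.phi[:500]))
        assert np.all(np.isnan(phase.phi[1500:]))

    def test_overlapping_breaths_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            B.compute_phase(breaths_from_arrays([0.0, 0.4], [0.5, 0.9]), 1000.0, 1.0)

    def test_single_breath_raises(self):
        with pytest.raises(ValueError, match="complete breath"):
            B.compute_phase(breaths_from_arrays([0.0], [0.5]), 1000.0, 1.0)


class TestSighs:
    def test_single_outlier_flagged_against_brute_force(self, rng):
        auc = np.ones(120) + 0.01 * rng.normal(size=120)
        auc[60] = 100.0
        onsets = np.arange(120) * 1.0
        br = breaths_from_arrays(onsets, onsets + 0.3, aucs=auc)
        flagged = B.detect_sighs(br)
        expect = brute_force_sigh_flags(auc)
        assert np.array_equal(flagged.is_sigh.values, expect)
        assert flagged.is_sigh.sum() == 1 and flagged.is_sigh.values[60]

    def test_identical_breaths_produce_no_flags(self):
        onsets = np.arange(80) * 1.0
        br = breaths_from_arrays(onsets, onsets + 0.3, aucs=np.ones(80))
        assert B.detect_sighs(br).is_sigh.sum() == 0

    def test_detector_is_pure(self, rng):
        auc = 1 + 0.1 * rng.normal(size=100)
        onsets = np.arange(100) * 1.0
        br = breaths_from_arrays(onsets, onsets + 0.3, aucs=auc)
        a = B.detect_sighs(br).is_sigh.values
        b = B.detect_sighs(br).is_sigh.values
        assert np.array_equal(a, b)


class TestGaspEpochs:
    def test_boundaries_match_brute_force(self):
        ibi = np.array([0.3] * 20 + [1.2] * 10 + [0.3] * 20)
        onsets = np.concatenate([[0.0], np.cumsum(ibi)[:-1]])
        br = breaths_from_arrays(onsets, onsets + 0.1)
        br["ibi"] = np.append(ibi[:-1], np.nan)
        epochs = B.detect_gasp_epochs(br)
        expect = brute_force_gasp_epochs(ibi[:-1])
        assert len(epochs) == len(expect) == 1
        assert (epochs.first_breath.iloc[0], epochs.last_breath.iloc[0]) == expect[0]

    def test_constant_short_ibis_give_no_epochs(self):
        onsets = np.arange(40) * 0.5
        br = breaths_from_arrays(onsets, onsets + 0.1)
        assert len(B.detect_gasp_epochs(br)) == 0

    def test_hysteresis_keeps_epoch_between_thresholds(self):
        # smoothed IBI oscillating between 0.9 and 1.1 after onset:
        # 0.9 > 0.85 so the epoch must persist
        ibi = np.array([0.3] * 10 + [1.2] * 7 + [0.9, 1.1] * 6 + [0.3] * 10)
        onsets = np.concatenate([[0.0], np.cumsum(ibi)[:-1]])
        br = breaths_from_arrays(onsets, onsets + 0.05)
        br["ibi"] = np.append(ibi[:-1], np.nan)
        epochs = B.detect_gasp_epochs(br)
        expect = brute_force_gasp_epochs(ibi[:-1])
        assert len(epochs) == 1
        assert (epochs.first_breath.iloc[0], epochs.last_breath.iloc[0]) == expect[0]

    def test_gasp_mode_recording_yields_epoch(self):
        ds = syn.generate_dataset(
            syn.GroundTruthConfig(duration=90.0, n_units=5, seed=4,
                                  perturbation="gasp")
        )
        trace = B.DiaphragmTrace(ds.diaphragm, 1000.0)
        table = B.detect_breaths(trace)
        epochs = B.detect_gasp_epochs(table)
        assert len(epochs) >= 1
        ids = B.gasp_epoch_ids(table, epochs)
        assert (ids >= 0).sum() > 0.5 * len(table)
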
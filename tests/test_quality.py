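import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from apneafusion.ingest import WindowSet, segment_record
from apneafusion.quality import (
    FilterConfig,
    acf_matrix,
    align_pairs,
    bandpass,
    compute_acf,
    reject_noisy,
    similarity_graph,
)
from apneafusion.synthetic import SimConfig, inject_artifacts, simulate_pair
from conftest import random_windowset


def brute_force_acf(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Independent time-domain oracle: sum_t x(t) x(t+l) / sum_t x(t)^2."""
    denom = float(np.sum(x * x))
    return np.array([np.sum(x[: len(x) - l] * x[l:]) for l in range(n_lags)]) / denom


def _wset(windows, fs=100.0):
    n = windows.shape[0]
    return WindowSet(windows, np.zeros(n, dtype=np.int8), fs, ["r"] * n,
                     np.arange(n, dtype=float))


class TestBandpass:
    def test_dc_removed(self):
        wset = _wset(np.full((3, 1100), 7.5))
        out = bandpass(wset)
        assert np.abs(out.windows).max() < 1e-6 * 7.5

    def test_passband_tone_preserved(self):
        """Oracle: the designed filter's own magnitude response at 10 Hz."""
        fs = 100.0
        t = np.arange(1100) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        cfg = FilterConfig()
        out = bandpass(_wset(x[None, :], fs), cfg)
        w, h = sps.sosfreqz(cfg.sos(fs), worN=[10.0], fs=fs)
        expected_gain = np.abs(h[0]) ** 2  # zero-phase applies the filter twice
        rms_ratio = np.sqrt(np.mean(out.windows**2) / np.mean(x**2))
        assert abs(rms_ratio - expected_gain) < 0.05
        assert abs(rms_ratio - 1.0) < 0.05

    def test_drift_tone_attenuated(self):
        fs = 100.0
        t = np.arange(4096) / fs
        x = np.sin(2 * np.pi * 0.1 * t)
        cfg = FilterConfig()
        out = bandpass(_wset(x[None, :], fs), cfg)
        w, h = sps.sosfreqz(cfg.sos(fs), worN=[0.1], fs=fs)
        expected_gain = np.abs(h[0]) ** 2
        rms_ratio = np.sqrt(np.mean(out.windows**2) / np.mean(x**2))
        assert rms_ratio < 0.10
        assert rms_ratio < expected_gain + 0.05

    def test_high_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_wset(np.ones((2, 100)), fs=60.0), FilterConfig(high_hz=40.0))


class TestAcf:
    def test_lag0_is_one(self, rng):
        acf = compute_acf(rng.standard_normal(128))
        assert acf[0] == pytest.approx(1.0)

    def test_reversal_symmetry(self, rng):
        x = rng.standard_normal(200)
        np.testing.assert_allclose(compute_acf(x), compute_acf(x[::-1]), atol=1e-10)

    def test_matches_brute_force_64(self, rng):
        x = rng.standard_normal(64)
        np.testing.assert_allclose(compute_acf(x), brute_force_acf(x, 64), atol=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(8, 256), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_any_length(self, n, seed):
        x = np.random.default_rng(seed).standard_normal(n)
        np.testing.assert_allclose(compute_acf(x), brute_force_acf(x, n), atol=1e-8)

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            compute_acf(np.zeros(32))


class TestSimilarityGraph:
    def test_identical_vectors(self):
        a = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        sim, w = similarity_graph(a)
        assert sim[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(sim, sim.T)
        np.testing.assert_allclose(np.diag(sim), 1.0)

    def test_orthogonal_vectors(self):
        sim, _ = similarity_graph(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert sim[0, 1] == pytest.approx(0.0)

    def test_closed_form_45_degrees(self):
        sim, w = similarity_graph(np.array([[1.0, 0.0], [1.0, 1.0]]))
        assert sim[0, 1] == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-9)
        assert w[0] == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-9)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            similarity_graph(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_weights_are_degree_sums(self, rng):
        acfs = rng.standard_normal((6, 10))
        sim, w = similarity_graph(acfs)
        np.testing.assert_allclose(w, sim.sum(axis=1) - 1.0)


class TestRejectNoisy:
    def test_tie_break_stable_on_identical_windows(self):
        wset = _wset(np.tile(np.sin(np.arange(100) / 3.0), (100, 1)))
        kept, report = reject_noisy(wset)
        assert len(kept) == 95
        np.testing.assert_array_equal(report.kept_indices, np.arange(95))

    def test_retention_count_ceil(self, rng):
        wset = _wset(rng.standard_normal((40, 64)) + 0.5)
        kept, report = reject_noisy(wset)
        assert len(kept) == 38  # ceil(0.95 * 40)
        assert report.keep_mask.sum() == 38

    def test_minimum_batch_enforced(self, rng):
        with pytest.raises(ValueError, match=">= 20"):
            reject_noisy(_wset(rng.standard_normal((10, 32))))

    def test_artifact_recovery_median_over_seeds(self):
        """>= 4 of 5 injected artifact spans land in the 5 discarded windows."""
        from apneafusion.quality import bandpass as bp

        recovered = []
        for seed in range(10):
            cfg = SimConfig(duration_s=1100.0, apnea_event_rate=20.0, seed=seed)
            ecg, _ = simulate_pair(cfg)
            dirty, truth = inject_artifacts(ecg, 0.05, seed=seed + 100)
            from apneafusion.ingest import SegmentationConfig

            wset = segment_record(dirty, SegmentationConfig(window_s=11.0, overlap_s=0.0))
            wset = bp(wset, FilterConfig())
            _, report = reject_noisy(wset, 0.95)
            recovered.append(len(set(report.discarded_indices) & set(truth)))
        assert np.median(recovered) >= 4

    def test_clean_window_outweighs_artifact(self, rng):
        """Duplicated clean periodic windows get higher degree than noise bursts."""
        clean = np.sin(np.arange(256) / 4.0)
        windows = np.tile(clean, (25, 1)) + 0.01 * rng.standard_normal((25, 256))
        windows[5] = 5.0 * rng.standard_normal(256)  # artifact
        _, report = reject_noisy(_wset(windows), 0.95, n_lags=100)
        assert report.weights[5] == report.weights.min()
        assert not report.keep_mask[5]

    def test_clean_similarity_exceeds_artifact_similarity(self, sim_pair):
        _, ecg, _ = sim_pair
        from apneafusion.ingest import SegmentationConfig

        dirty, truth = inject_artifacts(ecg, 0.10, seed=3)
        wset = bandpass(segment_record(dirty, SegmentationConfig(window_s=11.0, overlap_s=0.0)))
        acfs = acf_matrix(wset.windows, int(wset.fs))
        sim, _ = similarity_graph(acfs)
        clean = [i for i in range(len(wset)) if i not in truth]
        c0, c1 = clean[0], clean[1]
        assert sim[c0, c1] > sim[c0, truth[0]]


def test_align_pairs_intersects_start_times(rng):
    ecg = random_windowset(rng, n=10)
    spo2 = random_windowset(rng, n=10, fs=8.0)
    spo2 = spo2.replace(labels=ecg.labels.copy())
    ecg_sub = ecg.take([0, 2, 4, 6, 8])
    spo2_sub = spo2.take([2, 3, 4, 5, 6])
    a, b = align_pairs(ecg_sub, spo2_sub)
    assert a.pair_keys() == b.pair_keys()
    assert [int(t) for t in a.start_times_s] == [2, 4, 6]
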
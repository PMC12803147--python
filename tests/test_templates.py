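import numpy as np
import pytest

from emgsort import (
    MorphConfig,
    MotorPool,
    SpikeTrains,
    compute_temporal_components,
    detect_spikes_by_convolution,
    extract_nonoverlapping_crossings,
    make_channel_map,
    make_force_signal,
    make_simple_templates,
    make_synthetic_basis,
    reject_outlier_waveforms,
    superpose_spikes,
)
from emgsort.templates import WaveformSet

FS = 30000.0
NT = 61


def _spike_shape(nt=NT, width=6.0):
    """Biphasic test waveform with peak magnitude 1 at sample nt//3."""
    t = np.arange(nt, dtype=float)
    c = nt // 3
    w = np.exp(-0.5 * ((t - c) / width) ** 2) * np.cos(2 * np.pi * (t - c) / (4 * width))
    return w / np.max(np.abs(w))


def _plant(times_and_channels, amp=8.0, n=30000, n_ch=4, noise_sd=0.5, seed=0):
    rng = np.random.default_rng(seed)
    D = rng.normal(0.0, noise_sd, size=(n, n_ch))
    shape = _spike_shape()
    nt0 = NT // 3
    for t, c, a in times_and_channels:
        D[t - nt0: t - nt0 + NT, c] += a * shape
    return D


class TestExtraction:
    def test_all_below_threshold_empty(self):
        D = np.random.default_rng(0).normal(0, 0.1, size=(20000, 4))
        with pytest.warns(UserWarning, match="no non-overlapping"):
            wset = extract_nonoverlapping_crossings(D, [6.0], FS)
        assert len(wset) == 0

    def test_isolated_spikes_recovered(self):
        plants = [(5000, 1, 8.0), (12000, 2, 9.0), (20000, 0, 10.0)]
        D = _plant(plants, noise_sd=0.3)
        wset = extract_nonoverlapping_crossings(D, [6.0], FS)
        assert len(wset) == 3
        for t, c, _ in plants:
            hit = np.abs(wset.time_of_origin - t) <= 1
            assert hit.any()
            assert wset.channel_of_origin[hit][0] == c

    def test_close_pair_both_excluded(self):
        """Two spikes 0.5 ms apart on one channel violate isolation."""
        sep = int(0.5e-3 * FS)
        D = _plant([(10000, 1, 8.0), (10000 + sep, 1, 8.0)], noise_sd=0.2)
        wset = extract_nonoverlapping_crossings(D, [6.0], FS)
        assert len(wset) == 0

    def test_multithreshold_aggregation_is_superset(self):
        plants = [(4000, 0, 7.0), (10000, 2, 13.0), (17000, 1, 7.5), (24000, 3, 14.0)]
        D = _plant(plants, noise_sd=0.3)
        lo = extract_nonoverlapping_crossings(D, [6.0], FS)
        hi = extract_nonoverlapping_crossings(D, [9.0], FS)
        both = extract_nonoverlapping_crossings(D, [6.0, 9.0], FS)
        keys = set(zip(both.channel_of_origin, both.time_of_origin))
        for single in (lo, hi):
            assert set(zip(single.channel_of_origin, single.time_of_origin)) <= keys

    def test_no_duplicate_entries(self):
        D = _plant([(8000, 1, 12.0)], noise_sd=0.2)
        wset = extract_nonoverlapping_crossings(D, [3.0, 6.0, 9.0], FS)
        assert len(wset) == 1

    def test_nskip_skips_batches(self):
        plants = [(5000, 1, 9.0), (65000, 1, 9.0)]  # second lands in batch 1
        D = _plant(plants, n=120000, noise_sd=0.2)
        wset = extract_nonoverlapping_crossings(
            D, [6.0], FS, nskip=2, batch_size=60000
        )
        assert np.all(wset.time_of_origin < 60000)

    def test_peak_aligned_at_third(self):
        D = _plant([(9000, 2, 9.0)], noise_sd=0.1)
        wset = extract_nonoverlapping_crossings(D, [6.0], FS)
        peak = int(np.argmax(np.abs(wset.waveforms[0])))
        assert peak == NT // 3


class TestOutlierRejection:
    def _wset(self, waveforms):
        n = len(waveforms)
        return WaveformSet(
            waveforms=np.asarray(waveforms),
            channel_of_origin=np.zeros(n, np.int64),
            time_of_origin=np.arange(n, dtype=np.int64) * 100,
            threshold_that_found_it=np.full(n, 6.0),
        )

    def test_planted_outliers_removed(self, rng):
        c1 = rng.normal(0.0, 0.1, size=(200, NT))
        c2 = 10.0 + rng.normal(0.0, 0.1, size=(200, NT))
        far = rng.uniform(50, 100, size=(5, NT)) * rng.choice([-1, 1], size=(5, 1))
        wset = self._wset(np.vstack([c1, c2, far]))
        kept = reject_outlier_waveforms(wset, min_cluster_size=20)
        kept_idx = set(wset.time_of_origin.tolist()) & set(kept.time_of_origin.tolist())
        assert len(kept) >= 0.95 * 400
        assert all(t < 400 * 100 for t in kept.time_of_origin)  # all 5 far points gone

    def test_homogeneous_cluster_mostly_retained(self, rng):
        wset = self._wset(rng.normal(0.0, 0.1, size=(300, NT)))
        kept = reject_outlier_waveforms(wset)
        assert len(kept) >= 0.90 * 300

    def test_output_subset_of_input(self, rng):
        wset = self._wset(rng.normal(size=(100, NT)))
        kept = reject_outlier_waveforms(wset)
        in_keys = set(zip(wset.channel_of_origin, wset.time_of_origin))
        out_keys = set(zip(kept.channel_of_origin, kept.time_of_origin))
        assert out_keys <= in_keys

    def test_too_few_waveforms_passthrough(self, rng):
        wset = self._wset(rng.normal(size=(5, NT)))
        with pytest.warns(UserWarning, match="min_cluster_size"):
            kept = reject_outlier_waveforms(wset, min_cluster_size=20)
        assert kept is wset


class TestTemporalComponents:
    def test_orthonormal(self, rng):
        W = compute_temporal_components(rng.normal(size=(200, NT)), n_pcs=9)
        np.testing.assert_allclose(W @ W.T, np.eye(9), atol=1e-8)

    def test_more_components_never_worse(self, rng):
        X = rng.normal(size=(300, NT)) @ np.diag(np.linspace(2, 0.1, NT))
        sse = {}
        for k in (6, 9):
            W = compute_temporal_components(X, n_pcs=k)
            sse[k] = np.sum((X - X @ W.T @ W) ** 2)
        assert sse[9] <= sse[6]

    def test_rank_deficient_padded_with_warning(self):
        X = np.outer(np.arange(20.0), np.ones(NT))  # rank 1
        with pytest.warns(UserWarning, match="rank"):
            W = compute_temporal_components(X, n_pcs=4)
        np.testing.assert_allclose(W @ W.T, np.eye(4), atol=1e-8)

    def test_too_few_waveforms_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_temporal_components(rng.normal(size=(5, NT)), n_pcs=9)


class TestSimpleTemplates:
    def test_recovers_distinct_repeated_shapes(self, rng):
        shapes = np.array([np.roll(_spike_shape(), 3 * k) for k in range(9)])
        X = np.repeat(shapes, 30, axis=0)
        wset = WaveformSet(
            waveforms=X,
            channel_of_origin=np.zeros(len(X), np.int64),
            time_of_origin=np.arange(len(X), dtype=np.int64),
            threshold_that_found_it=np.full(len(X), 6.0),
        )
        tpl = make_simple_templates(wset, n_templates=9, seed=0)
        # every source shape appears among the peak-normalized centers
        for s in shapes:
            s_norm = s / np.max(np.abs(s))
            dists = np.min(np.sum((tpl.shapes - s_norm) ** 2, axis=1))
            assert dists < 1e-6

    def test_kmeans_beats_random_assignments(self, rng):
        X = rng.normal(size=(150, NT))
        wset = WaveformSet(
            waveforms=X,
            channel_of_origin=np.zeros(150, np.int64),
            time_of_origin=np.arange(150, dtype=np.int64),
            threshold_that_found_it=np.full(150, 6.0),
        )
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=9, n_init=10, random_state=0).fit(X)
        for trial in range(100):
            labels = rng.integers(0, 9, size=150)
            sse = sum(
                np.sum((X[labels == k] - X[labels == k].mean(axis=0)) ** 2)
                for k in range(9)
                if np.any(labels == k)
            )
            assert km.inertia_ <= sse + 1e-6


class TestConvolutionalDetection:
    def test_zero_data_no_detections(self):
        tpl = make_simple_templates(
            WaveformSet(
                waveforms=np.random.default_rng(0).normal(size=(50, NT)),
                channel_of_origin=np.zeros(50, np.int64),
                time_of_origin=np.arange(50, dtype=np.int64),
                threshold_that_found_it=np.full(50, 6.0),
            ),
            n_templates=3,
            seed=0,
        )
        det = detect_spikes_by_convolution(
            np.zeros((10000, 4)), tpl, make_channel_map(4)
        )
        assert len(det) == 0

    def test_planted_spike_detected_once(self):
        shape = _spike_shape()
        X = np.repeat(shape[None, :], 30, axis=0)
        tpl = make_simple_templates(
            WaveformSet(
                waveforms=X,
                channel_of_origin=np.zeros(30, np.int64),
                time_of_origin=np.arange(30, dtype=np.int64),
                threshold_that_found_it=np.full(30, 6.0),
            ),
            n_templates=1,
            seed=0,
        )
        rng = np.random.default_rng(1)
        D = rng.normal(0, 1.0, size=(20000, 4))
        t0 = 9000
        spatial = np.exp(-0.5 * ((np.arange(4) - 1) * 2.0 / 10.0) ** 2)
        D[t0 - NT // 3: t0 - NT // 3 + NT] += 20.0 * np.outer(shape, spatial)
        det = detect_spikes_by_convolution(
            D, tpl, make_channel_map(4), Th_universal=9.0
        )
        assert len(det) == 1
        assert abs(int(det["time"].iloc[0]) - t0) <= 1

    def test_end_to_end_recovers_sparse_ground_truth(self):
        """Template chain finds >= 90% of spikes of well-separated units."""
        basis = make_synthetic_basis(5, 8, nt=NT, max_delay=3, seed=21,
                                     amplitude_range=(4.0, 8.0))
        rng = np.random.default_rng(2)
        trains = []
        t = 2000
        for u in range(5):
            ts = []
            for _ in range(40):
                ts.append(t)
                t += rng.integers(400, 700)
            trains.append(np.array(ts, dtype=np.int64))
            t = 2000 + (u + 1) * 97  # interleave units, far apart in time
        duration = int(max(map(np.max, trains))) + 2000
        st = SpikeTrains(trains=[np.sort(x) for x in trains], duration=duration,
                         sampling_rate=FS)
        D = superpose_spikes(duration, st, basis, MorphConfig(gain_sd=0.05), seed=3)
        D += rng.normal(0, 0.3, size=D.shape)
        mads = np.median(np.abs(D - np.median(D, axis=0)), axis=0) / 0.6745
        Dw = D / mads  # variance-normalize per channel
        wset = extract_nonoverlapping_crossings(Dw, [6.0, 9.0, 12.0, 15.0], FS,
                                                nskip=1)
        wset = reject_outlier_waveforms(wset)
        tpl = make_simple_templates(wset, n_templates=5, seed=0)
        det = detect_spikes_by_convolution(Dw, tpl, make_channel_map(8),
                                           Th_universal=9.0)
        det_times = np.sort(det["time"].to_numpy())
        tol = int(1e-3 * FS)
        all_truth = np.sort(np.concatenate(st.trains))
        hits = sum(
            bool(np.any(np.abs(det_times - t0) <= tol)) for t0 in all_truth
        )
        assert hits >= 0.9 * all_truth.size
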
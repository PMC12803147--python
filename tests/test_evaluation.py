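import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgsort import (
    align_matched_pair,
    compute_metrics,
    error_rate_reduction,
    evaluate_sorting,
    greedy_match_clusters,
    match_spike_times,
    select_overlapping_spikes,
    summarize_sweep,
)
from emgsort.evaluation import (
    ALIGN_BIN_MS,
    N_ALIGN_CANDIDATES,
    _bin_counts,
    _binned_accuracy,
    candidate_shifts,
)

FS = 30000.0


def _poisson_train(rate_hz, duration_s, rng, refractory_ms=1.5):
    """Refractory-respecting random train in milliseconds."""
    t, out = 0.0, []
    while True:
        t += rng.exponential(1000.0 / rate_hz) + refractory_ms
        if t >= duration_s * 1000.0:
            return np.array(out)
        out.append(t)


class TestGreedyMatching:
    def test_relabeled_truth_recovered(self, rng):
        truth = [_poisson_train(10, 30, rng) for _ in range(4)]
        sorted_ms = {7: truth[2], 3: truth[0], 9: truth[1], 1: truth[3]}
        pairing = greedy_match_clusters(truth, sorted_ms)
        assert pairing == {0: 3, 1: 9, 2: 7, 3: 1}

    def test_empty_sorter_output(self, rng):
        truth = [_poisson_train(10, 10, rng) for _ in range(3)]
        pairing = greedy_match_clusters(truth, {})
        assert pairing == {0: None, 1: None, 2: None}

    def _greedy_oracle(self, truth, sorted_ms):
        """Exhaustive search for the lexicographically best assignment."""
        horizon = max(
            [t[-1] for t in truth if t.size]
            + [s[-1] for s in sorted_ms.values() if s.size],
            default=0.0,
        )
        n_bins = int(np.floor(horizon / 10.0)) + 1
        tb = [_bin_counts(t, 10.0, n_bins) for t in truth]
        ids = sorted(sorted_ms)
        sb = {c: _bin_counts(sorted_ms[c], 10.0, n_bins) for c in ids}
        best_vec, best_assign = None, None
        k = min(len(truth), len(ids))
        for units in itertools.permutations(range(len(truth)), k):
            for clusters in itertools.permutations(ids, k):
                accs = sorted(
                    (_binned_accuracy(tb[u], sb[c]) for u, c in zip(units, clusters)),
                    reverse=True,
                )
                if best_vec is None or accs > best_vec:
                    best_vec = accs
                    best_assign = dict(zip(units, clusters))
        return best_vec

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_on_small_instances(self, trial):
        rng = np.random.default_rng(trial)
        n_truth = rng.integers(1, 5)
        n_sort = rng.integers(1, 6)
        truth = [_poisson_train(rng.uniform(5, 20), 5, rng) for _ in range(n_truth)]
        sorted_ms = {}
        for c in range(n_sort):
            src = truth[rng.integers(0, n_truth)]
            keep = rng.random(src.size) > rng.uniform(0, 0.5)
            sorted_ms[c] = src[keep]
        pairing = greedy_match_clusters(truth, sorted_ms)
        horizon = max(
            [t[-1] for t in truth if t.size]
            + [s[-1] for s in sorted_ms.values() if s.size],
            default=0.0,
        )
        n_bins = int(np.floor(horizon / 10.0)) + 1
        tb = [_bin_counts(t, 10.0, n_bins) for t in truth]
        sb = {c: _bin_counts(s, 10.0, n_bins) for c, s in sorted_ms.items()}
        got_vec = sorted(
            (
                _binned_accuracy(tb[u], sb[c])
                for u, c in pairing.items()
                if c is not None
            ),
            reverse=True,
        )
        assert got_vec == self._greedy_oracle(truth, sorted_ms)


class TestAlignment:
    def test_identical_trains_zero_shift(self, rng):
        t = _poisson_train(20, 10, rng)
        assert align_matched_pair(t, t) == 0

    def test_planted_delay_recovered(self, rng):
        t = _poisson_train(20, 10, rng)
        assert align_matched_pair(t, t + 1.5) == -15

    def test_enumerates_41_candidates(self):
        shifts = candidate_shifts()
        assert len(shifts) == N_ALIGN_CANDIDATES == 41
        assert shifts[0] == -20 and shifts[-1] == 20

    def test_empty_train_shift_zero(self):
        assert align_matched_pair(np.array([]), np.array([1.0])) == 0

    @pytest.mark.parametrize("delay_ms", [-2.0, -0.7, 0.3, 2.0])
    def test_recovers_delays_across_range(self, delay_ms, rng):
        t = _poisson_train(30, 10, rng)
        shift = align_matched_pair(t, t + delay_ms)
        assert shift == -round(delay_ms / ALIGN_BIN_MS)


class TestSpikeTimeMatching:
    def test_identical(self):
        t = np.array([5.0, 10.0, 20.0])
        assert match_spike_times(t, t) == (3, 0, 0)

    def test_closest_wins_extra_is_fp(self):
        n_match, fp, fn = match_spike_times(np.array([10.0]), np.array([9.7, 10.4]))
        assert (n_match, fp, fn) == (1, 1, 0)

    def test_jitter_within_tolerance_all_matched(self, rng):
        t = _poisson_train(20, 20, rng, refractory_ms=2.5)
        jittered = np.sort(t + rng.uniform(-0.9, 0.9, size=t.size))
        n_match, fp, fn = match_spike_times(t, jittered)
        assert fp == 0 and fn == 0 and n_match == t.size

    def test_one_to_one_under_contention(self):
        # two truth spikes, one sorted spike between them: only one match
        n_match, fp, fn = match_spike_times(np.array([10.0, 10.8]), np.array([10.4]))
        assert (n_match, fp, fn) == (1, 0, 1)


class TestMetrics:
    def test_perfect(self):
        assert compute_metrics(10, 10, 10) == (1.0, 1.0, 1.0)

    def test_worked_example(self):
        p, r, a = compute_metrics(10, 9, 8)
        assert (p, r, a) == (8 / 9, 0.8, 8 / 11)

    def test_no_matches(self):
        assert compute_metrics(10, 9, 0) == (0.0, 0.0, 0.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(5, 5, 6)

    @given(
        n_truth=st.integers(0, 1000),
        n_sort=st.integers(0, 1000),
        frac=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=200)
    def test_accuracy_bounded_by_precision_and_recall(self, n_truth, n_sort, frac):
        n_match = int(frac * min(n_truth, n_sort))
        p, r, a = compute_metrics(n_truth, n_sort, n_match)
        assert 0 <= a <= min(p, r) + 1e-12 <= 1 + 1e-12
        if p == r == 1 and n_truth > 0:
            assert a == 1


class TestOverlapSelection:
    def test_single_unit_empty(self):
        out = select_overlapping_spikes([np.array([1.0, 5.0, 9.0])], 1.0)
        assert out[0].size == 0

    def test_matches_brute_force(self, rng):
        trains = [np.sort(rng.uniform(0, 100, size=30)) for _ in range(3)]
        window = 1.0
        out = select_overlapping_spikes(trains, window)
        for u in range(3):
            expected = [
                t
                for t in trains[u]
                if any(
                    abs(t - s) <= window
                    for v in range(3)
                    if v != u
                    for s in trains[v]
                )
            ]
            np.testing.assert_allclose(out[u], expected)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            select_overlapping_spikes([np.array([1.0])], 0.0)


class TestErrorRateReduction:
    def test_rat_worked_example(self):
        assert error_rate_reduction(15.9, 48.9) == pytest.approx(67.5, abs=0.05)

    def test_monkey_worked_example(self):
        assert error_rate_reduction(17.0, 33.9) == pytest.approx(49.9, abs=0.05)

    def test_equal_rates_zero(self):
        assert error_rate_reduction(3.0, 3.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            error_rate_reduction(1.0, 0.0)


class TestSweepSummary:
    def test_single_run(self):
        s = summarize_sweep([[0.5, 1.0]])
        assert s == {"median": 0.75, "mean": 0.75, "sd": 0.0}

    def test_three_runs_median(self):
        s = summarize_sweep([[0.9], [0.8], [0.7]])
        assert s["median"] == pytest.approx(0.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_sweep([])
        with pytest.raises(ValueError):
            summarize_sweep([[]])


class TestEvaluatorSelfConsistency:
    def _truth_samples(self, rng, n_units=4, duration_s=30):
        return [
            (_poisson_train(12, duration_s, rng) / 1000.0 * FS).astype(np.int64)
            for _ in range(n_units)
        ]

    def test_truth_fed_back_scores_one(self, rng):
        truth = self._truth_samples(rng)
        sorted_out = {10 + u: t for u, t in enumerate(truth)}
        report = evaluate_sorting(truth, sorted_out, FS)
        for row in report.rows:
            assert row["A"] == 1.0 and row["P"] == 1.0 and row["R"] == 1.0

    def test_shifted_and_jittered_truth_scores_one(self, rng):
        truth = self._truth_samples(rng)
        shift = int(1.8e-3 * FS)  # 1.8 ms global offset
        jitter_max = int(0.6e-3 * FS)
        sorted_out = {
            u: np.sort(t + shift + rng.integers(-jitter_max, jitter_max, t.size))
            for u, t in enumerate(truth)
        }
        report = evaluate_sorting(truth, sorted_out, FS)
        for row in report.rows:
            assert row["A"] == 1.0

    def test_overlap_restricted_scores_reported(self, rng):
        truth = self._truth_samples(rng, n_units=3)
        sorted_out = {u: t for u, t in enumerate(truth)}
        report = evaluate_sorting(truth, sorted_out, FS, overlap_window_ms=1.0)
        df = report.to_frame()
        assert {"A_overlap", "N_truth_overlap"} <= set(df.columns)
        for row in report.rows:
            if row["N_truth_overlap"] > 0:
                assert row["A_overlap"] == 1.0

    def test_dropped_spikes_lower_recall_only(self, rng):
        truth = self._truth_samples(rng, n_units=2)
        sorted_out = {u: t[::2] for u, t in enumerate(truth)}  # drop half
        report = evaluate_sorting(truth, sorted_out, FS)
        for row in report.rows:
            assert row["P"] == 1.0
            assert row["R"] == pytest.approx(0.5, abs=0.01)
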
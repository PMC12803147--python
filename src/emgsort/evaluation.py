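"""Ground-truth evaluation of a sorter's output.

Scoring proceeds in three stages of increasing time resolution. First,
clusters are paired to ground-truth units greedily on a coarse (10 ms)
binned accuracy, without replacement, in descending order of accuracy.
Second, each matched pair is time-aligned by maximizing the Pearson
correlation of 0.1 ms binned trains over exactly 41 candidate shifts
(±20 bins = ±2 ms); sorters may place spike times anywhere on the waveform,
so a global per-pair offset is expected. Third, shifted spike times are
matched one-to-one within ±1 ms; when several sorted spikes qualify for one
truth spike only the closest counts as a true positive and the rest are
false positives.

Precision, recall and accuracy follow the standard definitions
``P = N_match/N_sort``, ``R = N_match/N_truth`` and
``A = N_match / (N_truth + N_sort - N_match)``. An overlap-restricted
variant rescores only truth spikes with a different-unit neighbor within
half a template window, the regime where waveform superposition makes
sorting hardest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MatchReport",
    "greedy_match_clusters",
    "align_matched_pair",
    "match_spike_times",
    "compute_metrics",
    "select_overlapping_spikes",
    "error_rate_reduction",
    "summarize_sweep",
    "evaluate_sorting",
    "candidate_shifts",
    "N_ALIGN_CANDIDATES",
]

ALIGN_BIN_MS = 0.1
ALIGN_MAX_SHIFT_BINS = 20
N_ALIGN_CANDIDATES = 2 * ALIGN_MAX_SHIFT_BINS + 1  # 41 shifted copies


def candidate_shifts(max_shift_bins: int = ALIGN_MAX_SHIFT_BINS) -> np.ndarray:
    """The integer bin shifts the alignment stage enumerates."""
    return np.arange(-max_shift_bins, max_shift_bins + 1)


def _bin_counts(times_ms: np.ndarray, bin_ms: float, n_bins: int) -> np.ndarray:
    idx = np.floor(times_ms / bin_ms).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    return np.bincount(idx, minlength=n_bins)


def _binned_accuracy(a: np.ndarray, b: np.ndarray) -> float:
    match = int(np.minimum(a, b).sum())
    denom = int(a.sum()) + int(b.sum()) - match
    return match / denom if denom > 0 else 0.0


def greedy_match_clusters(
    truth_ms: list[np.ndarray],
    sorted_ms: dict[int, np.ndarray],
    bin_ms: float = 10.0,
) -> dict[int, int | None]:
    """Pair sorted clusters to truth units without replacement.

    Both sets are binned at ``bin_ms``; for every (truth, cluster) pair a
    binned accuracy is computed (per-bin matched count = min of the two
    counts), and the globally best unassigned pair is taken repeatedly.
    Unmatched truth units map to None.
    """
    if not truth_ms:
        raise ValueError("need at least one truth unit")
    horizon = max(
        [t[-1] for t in truth_ms if t.size] + [s[-1] for s in sorted_ms.values() if s.size],
        default=0.0,
    )
    n_bins = int(np.floor(horizon / bin_ms)) + 1
    tb = [_bin_counts(t, bin_ms, n_bins) for t in truth_ms]
    cluster_ids = sorted(sorted_ms)
    sb = {c: _bin_counts(sorted_ms[c], bin_ms, n_bins) for c in cluster_ids}
    scores = [
        (_binned_accuracy(tb[u], sb[c]), u, c)
        for u in range(len(truth_ms))
        for c in cluster_ids
    ]
    # descending accuracy; ties by truth index then cluster id for determinism
    scores.sort(key=lambda x: (-x[0], x[1], x[2]))
    pairing: dict[int, int | None] = {u: None for u in range(len(truth_ms))}
    used: set[int] = set()
    for _acc, u, c in scores:
        if pairing[u] is None and c not in used:
            pairing[u] = c
            used.add(c)
    return pairing


def align_matched_pair(
    truth_ms: np.ndarray,
    sorted_ms: np.ndarray,
    bin_ms: float = ALIGN_BIN_MS,
    max_shift_bins: int = ALIGN_MAX_SHIFT_BINS,
) -> int:
    """Best integer shift (in 0.1 ms bins) applied to the sorted train.

    Evaluates exactly ``2 * max_shift_bins + 1`` shifted copies and returns
    the shift maximizing the Pearson correlation of the binned trains; ties
    break toward zero shift. Empty trains give shift 0.
    """
    if truth_ms.size == 0 or sorted_ms.size == 0:
        return 0
    horizon = max(truth_ms[-1], sorted_ms[-1]) + max_shift_bins * bin_ms
    n_bins = int(np.floor(horizon / bin_ms)) + 1
    tb = _bin_counts(truth_ms, bin_ms, n_bins).astype(np.float64)
    best_shift, best_corr = 0, -np.inf
    for s in candidate_shifts(max_shift_bins):
        s = int(s)
        sb = _bin_counts(sorted_ms + s * bin_ms, bin_ms, n_bins).astype(np.float64)
        if tb.std() == 0 or sb.std() == 0:
            corr = 0.0
        else:
            corr = float(np.corrcoef(tb, sb)[0, 1])
        if corr > best_corr + 1e-12 or (
            abs(corr - best_corr) <= 1e-12 and abs(s) < abs(best_shift)
        ):
            best_corr, best_shift = corr, s
    return best_shift


def match_spike_times(
    truth_ms: np.ndarray, sorted_ms: np.ndarray, tol_ms: float = 1.0
) -> tuple[int, int, int]:
    """One-to-one spike matching within ±``tol_ms``.

    Candidate (truth, sorted) pairs within tolerance are taken greedily by
    ascending |Δt|, so each sorted spike serves at most one truth spike and
    the closest candidate wins. Returns ``(n_match, fp, fn)``.
    """
    truth_ms = np.asarray(truth_ms, dtype=np.float64)
    sorted_ms = np.asarray(sorted_ms, dtype=np.float64)
    pairs: list[tuple[float, int, int]] = []
    for i, t in enumerate(truth_ms):
        lo = np.searchsorted(sorted_ms, t - tol_ms, side="left")
        hi = np.searchsorted(sorted_ms, t + tol_ms, side="right")
        for j in range(lo, hi):
            dt = abs(sorted_ms[j] - t)
            if dt <= tol_ms:
                pairs.append((dt, i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_s: set[int] = set()
    n_match = 0
    for _dt, i, j in pairs:
        if i not in used_t and j not in used_s:
            used_t.add(i)
            used_s.add(j)
            n_match += 1
    return n_match, sorted_ms.size - n_match, truth_ms.size - n_match


def compute_metrics(n_truth: int, n_sort: int, n_match: int) -> tuple[float, float, float]:
    """Precision, recall and accuracy from the three counts; 0/0 -> 0."""
    if n_match > min(n_truth, n_sort) or min(n_truth, n_sort, n_match) < 0:
        raise ValueError("invalid counts: n_match must not exceed n_truth or n_sort")
    p = n_match / n_sort if n_sort else 0.0
    r = n_match / n_truth if n_truth else 0.0
    denom = n_truth + n_sort - n_match
    a = n_match / denom if denom else 0.0
    return p, r, a


def select_overlapping_spikes(
    truth_ms: list[np.ndarray], overlap_window_ms: float
) -> list[np.ndarray]:
    """Per unit, the truth spikes with a different-unit neighbor within ±window."""
    if overlap_window_ms <= 0:
        raise ValueError("overlap window must be positive")
    out = []
    for u, train in enumerate(truth_ms):
        others = [t for v, t in enumerate(truth_ms) if v != u and t.size]
        if not others or train.size == 0:
            out.append(np.empty(0, dtype=train.dtype if train.size else np.float64))
            continue
        pool = np.sort(np.concatenate(others))
        lo = np.searchsorted(pool, train - overlap_window_ms, side="left")
        hi = np.searchsorted(pool, train + overlap_window_ms, side="right")
        out.append(train[hi > lo])
    return out


def error_rate_reduction(e_new: float, e_ref: float) -> float:
    """Percent reduction in error rate relative to a reference: 100*(1 - e/e0)."""
    if e_ref <= 0:
        raise ValueError("reference error rate must be positive")
    return 100.0 * (1.0 - e_new / e_ref)


def summarize_sweep(per_run_unit_accuracies: list[list[float]]) -> dict[str, float]:
    """Median/mean/sd of cross-unit mean accuracies across sweep runs."""
    if not per_run_unit_accuracies:
        raise ValueError("need at least one run")
    means = []
    for accs in per_run_unit_accuracies:
        if len(accs) == 0:
            raise ValueError("run with empty unit accuracy list")
        means.append(float(np.mean(accs)))
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return {
        "median": float(np.median(means)),
        "mean": float(np.mean(means)),
        "sd": sd,
    }


@dataclass
class MatchReport:
    """Pairing, shifts and metrics for one evaluation run."""

    rows: list[dict] = field(default_factory=list)
    tolerance_ms: float = 1.0
    overlap_window_ms: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def mean_accuracy(self, overlap: bool = False) -> float:
        key = "A_overlap" if overlap else "A"
        vals = [r[key] for r in self.rows if r[key] is not None]
        return float(np.mean(vals)) if vals else 0.0

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate_sorting(
    truth_samples: list[np.ndarray],
    sorted_samples: dict[int, np.ndarray],
    sampling_rate: float,
    tol_ms: float = 1.0,
    overlap_window_ms: float | None = None,
) -> MatchReport:
    """Full three-stage evaluation of sorter output against ground truth.

    Spike times are sample indices; conversion to milliseconds uses
    ``sampling_rate``. When ``overlap_window_ms`` is given, each pair is
    additionally rescored on the truth subset with different-unit neighbors
    within the window, counting only sorted spikes attributable (within
    tolerance) to that subset.
    """
    truth_ms = [np.asarray(t) / sampling_rate * 1000.0 for t in truth_samples]
    sorted_ms = {
        c: np.asarray(s) / sampling_rate * 1000.0 for c, s in sorted_samples.items()
    }
    pairing = greedy_match_clusters(truth_ms, sorted_ms)
    overlap_subsets = (
        select_overlapping_spikes(truth_ms, overlap_window_ms)
        if overlap_window_ms
        else None
    )
    report = MatchReport(tolerance_ms=tol_ms, overlap_window_ms=overlap_window_ms)
    for u, t_ms in enumerate(truth_ms):
        cluster = pairing[u]
        row: dict = {
            "unit": u,
            "matched_cluster": cluster,
            "shift_bins": 0,
            "N_truth": int(t_ms.size),
            "N_sort": 0,
            "N_match": 0,
        }
        if cluster is not None:
            s_ms = sorted_ms[cluster]
            shift = align_matched_pair(t_ms, s_ms)
            shifted = s_ms + shift * ALIGN_BIN_MS
            n_match, _fp, _fn = match_spike_times(t_ms, shifted, tol_ms)
            row.update(shift_bins=shift, N_sort=int(s_ms.size), N_match=n_match)
        p, r, a = compute_metrics(row["N_truth"], row["N_sort"], row["N_match"])
        row.update(P=p, R=r, A=a)
        if overlap_subsets is not None:
            sub = overlap_subsets[u]
            if cluster is not None and sub.size:
                shifted = sorted_ms[cluster] + row["shift_bins"] * ALIGN_BIN_MS
                lo = np.searchsorted(shifted, sub - tol_ms, side="left")
                hi = np.searchsorted(shifted, sub + tol_ms, side="right")
                attributable = np.unique(
                    np.concatenate([np.arange(a_, b_) for a_, b_ in zip(lo, hi)])
                    if sub.size
                    else np.empty(0, dtype=np.int64)
                )
                s_sub = shifted[attributable]
                n_match_o, _, _ = match_spike_times(sub, s_sub, tol_ms)
                p_o, r_o, a_o = compute_metrics(sub.size, s_sub.size, n_match_o)
                row.update(
                    N_truth_overlap=int(sub.size),
                    N_sort_overlap=int(s_sub.size),
                    N_match_overlap=n_match_o,
                    P_overlap=p_o,
                    R_overlap=r_o,
                    A_overlap=a_o,
                )
            else:
                row.update(
                    N_truth_overlap=int(sub.size),
                    N_sort_overlap=0,
                    N_match_overlap=0,
                    P_overlap=0.0,
                    R_overlap=0.0,
                    A_overlap=0.0,
                )
        else:
            row.update(A_overlap=None)
        report.rows.append(row)
    return report
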
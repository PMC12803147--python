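"""Recording-side preparation before template initialization.

Covers zero-phase band-pass (250-5000 Hz default) and line-noise notch
filtering, robust bad-channel rejection, ZCA whitening, the dense 1-D
channel map (2 um pitch), and cross-channel conduction-delay estimation and
removal. Delay correction addresses a property peculiar to intramuscular
arrays: a MUAP propagates along muscle fibers, so the same event arrives at
different channels up to a couple of milliseconds apart, which fragments
template matching if uncorrected. The estimator cross-correlates every
channel pair over integer lags within +/-2 ms, takes the correlation-
maximizing lag per pair, picks the reference channel whose row of best
correlations sums highest, and shifts every other channel by that row's lag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, iirnotch, sosfiltfilt, filtfilt

from .waveforms import estimate_channel_mads

__all__ = [
    "DelayPlan",
    "ChannelMap",
    "bandpass_filter",
    "notch_filter",
    "detect_bad_channels",
    "whiten",
    "estimate_channel_delays",
    "apply_channel_delays",
    "make_channel_map",
]


@dataclass
class DelayPlan:
    """Per-channel integer shifts that align conduction-delayed channels.

    ``shifts[c]`` is the lag (in samples) at which channel ``c`` best
    correlates with the reference channel; applying the plan advances each
    channel by its shift so all channels align with the reference.
    """

    reference_channel: int
    shifts: np.ndarray  # (n_channels,) int
    best_shift_matrix: np.ndarray  # (n_channels, n_channels) int
    correlation_matrix: np.ndarray  # (n_channels, n_channels, n_lags)
    max_lag: int
    sampling_rate: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "reference_channel": int(self.reference_channel),
                    "shifts": [int(s) for s in self.shifts],
                    "max_lag": int(self.max_lag),
                    "sampling_rate": self.sampling_rate,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DelayPlan":
        d = json.loads(Path(path).read_text())
        shifts = np.asarray(d["shifts"], dtype=np.int64)
        n = len(shifts)
        return cls(
            reference_channel=int(d["reference_channel"]),
            shifts=shifts,
            best_shift_matrix=np.zeros((n, n), dtype=np.int64),
            correlation_matrix=np.zeros((n, n, 0)),
            max_lag=int(d["max_lag"]),
            sampling_rate=float(d["sampling_rate"]),
        )


@dataclass
class ChannelMap:
    """Dense linear probe geometry (1-D positions in micrometers)."""

    positions: np.ndarray
    spacing: float = 2.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        d = np.diff(self.positions)
        if d.size and (np.any(d <= 0) or not np.allclose(d, self.spacing)):
            raise ValueError("positions must increase uniformly by the spacing")


def make_channel_map(n_channels: int, spacing: float = 2.0) -> ChannelMap:
    """Dense linear channel map of minimal size: 0, 2, 4, ... um."""
    if n_channels < 1:
        raise ValueError("need at least one channel")
    return ChannelMap(positions=np.arange(n_channels) * spacing, spacing=spacing)


def bandpass_filter(
    D: np.ndarray, sampling_rate: float, low: float = 250.0, high: float = 5000.0
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    nyq = sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band [{low}, {high}] for fs={sampling_rate}")
    sos = butter(4, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(D, dtype=np.float64), axis=0)


def notch_filter(
    D: np.ndarray, sampling_rate: float, freq: float = 60.0, q: float = 30.0
) -> np.ndarray:
    """Zero-phase narrow-band rejection at the line frequency (60 or 50 Hz)."""
    if not 0 < freq < sampling_rate / 2.0:
        raise ValueError(f"invalid notch frequency {freq} for fs={sampling_rate}")
    b, a = iirnotch(freq, q, fs=sampling_rate)
    return filtfilt(b, a, np.asarray(D, dtype=np.float64), axis=0)


def detect_bad_channels(D: np.ndarray, method: str = "mad5") -> np.ndarray:
    """Boolean keep-mask; channels with outlying robust deviation dropped.

    ``method`` is ``'mad'``/``'std'`` optionally suffixed with a threshold
    (default 5): a channel is rejected when its statistic exceeds
    threshold x the cross-channel median of that statistic.
    """
    D = np.asarray(D)
    if D.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    if method.startswith("mad"):
        suffix = method[3:]
        stats = estimate_channel_mads(D)
    elif method.startswith("std"):
        suffix = method[3:]
        stats = np.std(D, axis=0)
    else:
        raise ValueError(f"unknown bad-channel method {method!r}")
    thresh = float(suffix) if suffix else 5.0
    ref = np.median(stats)
    if ref == 0:
        return np.ones(D.shape[1], dtype=bool)
    return stats <= thresh * ref


def whiten(
    D: np.ndarray, whitening_range: int = 32, eps: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric (ZCA) whitening of channel amplitudes.

    Returns ``(D_white, Wm, Wm_inv)`` with output channel covariance near
    identity. ``whitening_range`` limits the estimate to that many nearest
    channels per row (use >= n_channels for the full matrix, the recommended
    setting for small arrays). Rank-deficient covariances are regularized
    with a warning.
    """
    D = np.asarray(D, dtype=np.float64)
    n_ch = D.shape[1]
    Dc = D - D.mean(axis=0, keepdims=True)
    cov = Dc.T @ Dc / D.shape[0]
    if whitening_range < n_ch:
        # zero covariance entries beyond the local neighborhood
        half = whitening_range // 2
        mask = np.abs(np.subtract.outer(np.arange(n_ch), np.arange(n_ch))) <= half
        cov = cov * mask
        cov = (cov + cov.T) / 2
    evals, evecs = np.linalg.eigh(cov)
    if np.min(evals) < eps * np.max(evals):
        warnings.warn("rank-deficient channel covariance; regularizing", stacklevel=2)
    evals = np.clip(evals, eps * max(np.max(evals), eps), None)
    Wm = evecs @ np.diag(evals**-0.5) @ evecs.T
    Wm_inv = evecs @ np.diag(evals**0.5) @ evecs.T
    return Dc @ Wm, Wm, Wm_inv


def _pairwise_lag_correlations(D: np.ndarray, max_lag: int) -> np.ndarray:
    """Pearson correlation for all channel pairs at integer lags.

    ``corr[a, b, i]`` correlates ``a[t]`` with ``b[t + lag_i]`` over the
    overlapping samples, lags running -max_lag..+max_lag. Zero-variance
    segments yield correlation 0.
    """
    D = np.asarray(D, dtype=np.float64)
    n, c = D.shape
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.zeros((c, c, lags.size))
    for i, k in enumerate(lags):
        if k >= 0:
            A, B = D[: n - k], D[k:]
        else:
            A, B = D[-k:], D[: n + k]
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        na = np.sqrt(np.sum(Ac**2, axis=0))
        nb = np.sqrt(np.sum(Bc**2, axis=0))
        denom = np.outer(na, nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            cmat = (Ac.T @ Bc) / denom
        cmat[~np.isfinite(cmat)] = 0.0
        corr[:, :, i] = cmat
    return corr


def _argmax_lag(values: np.ndarray, lags: np.ndarray) -> int:
    """Best lag with ties broken toward smaller |lag|, then negative lag."""
    best = np.max(values)
    cand = lags[np.isclose(values, best, rtol=0, atol=1e-12)]
    order = np.lexsort((cand, np.abs(cand)))  # |lag| primary, negative first
    return int(cand[order[0]])


def estimate_channel_delays(
    D: np.ndarray, sampling_rate: float, max_lag_ms: float = 2.0
) -> DelayPlan:
    """Estimate conduction delays by cross-channel correlation maximization.

    Builds the (channels x channels x lags) Pearson-correlation matrix over
    integer lags within ±``max_lag_ms``, takes the argmax lag per pair, and
    chooses as reference the channel whose best-correlation row sums
    highest (ties to the lowest channel index).
    """
    D = np.asarray(D, dtype=np.float64)
    if D.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    max_lag = int(round(max_lag_ms * sampling_rate / 1000.0))
    if D.shape[0] <= 2 * max_lag:
        raise ValueError("recording shorter than twice the maximum lag")
    lags = np.arange(-max_lag, max_lag + 1)
    corr = _pairwise_lag_correlations(D, max_lag)
    n_ch = D.shape[1]
    best_shift = np.zeros((n_ch, n_ch), dtype=np.int64)
    best_corr = np.zeros((n_ch, n_ch))
    for a in range(n_ch):
        for b in range(n_ch):
            best_shift[a, b] = _argmax_lag(corr[a, b], lags)
            best_corr[a, b] = np.max(corr[a, b])
    row_sums = best_corr.sum(axis=1)
    reference = int(np.argmax(row_sums))  # argmax takes the lowest index on ties
    return DelayPlan(
        reference_channel=reference,
        shifts=best_shift[reference].copy(),
        best_shift_matrix=best_shift,
        correlation_matrix=corr,
        max_lag=max_lag,
        sampling_rate=sampling_rate,
    )


def apply_channel_delays(D: np.ndarray, plan: DelayPlan) -> np.ndarray:
    """Advance each channel by its estimated delay; vacated edges become 0.

    A channel whose best lag is ``+k`` (it lags the reference by ``k``
    samples) is moved earlier by ``k`` so that events line up with the
    reference channel.
    """
    D = np.asarray(D, dtype=np.float64)
    if plan.shifts.shape[0] != D.shape[1]:
        raise ValueError("plan channel count mismatches data")
    n = D.shape[0]
    out = np.zeros_like(D)
    for c, k in enumerate(plan.shifts):
        k = int(k)
        if abs(k) >= n:
            raise ValueError(f"shift {k} exceeds data length {n}")
        if k == 0:
            out[:, c] = D[:, c]
        elif k > 0:
            out[: n - k, c] = D[k:, c]
        else:
            out[-k:, c] = D[: n + k, c]
    return out
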
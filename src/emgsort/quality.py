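"""Sort-quality metrics that require no ground truth.

Four per-cluster component scores, each in [0, 1], target the four error
modes a human curator screens for:

* type I (false positives): one minus the Llobet refractory-violation
  contamination estimate at a 1 ms refractory period;
* type II (false negatives): presence ratio (20 s bins, 0.5 x mean-rate
  threshold) times one minus the amplitude-histogram cutoff (32 bins);
* firing-rate validity: logistic penalties past 200 Hz on both the mean
  rate and the 5th-95th percentile rate range (0.5 s bins) — motor units do
  not fire that fast, so such clusters are artifacts;
* SNR: a logistic centered at SNR 4, below which sorting degrades sharply.

The per-cluster composite is the product of the four components, so any
single error mode drives the score toward zero; the overall sort score is
the mean of cluster composites and is used to rank parameter-sweep runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .waveforms import estimate_channel_mads

__all__ = [
    "QualityReport",
    "contamination_llobet",
    "type1_score",
    "presence_ratio",
    "amplitude_cutoff",
    "type2_score",
    "firing_rate_metrics",
    "firing_rate_score",
    "snr_score",
    "compute_snr",
    "composite_scores",
    "cluster_quality",
]


def contamination_llobet(
    times_s: np.ndarray,
    duration_s: float,
    refractory_ms: float = 1.0,
    censored_ms: float = 0.0,
) -> float:
    """Violation-based contamination estimate, clamped to [0, 1].

    Counts spike pairs with inter-spike interval in (censored, refractory]
    and inverts the expected violation count of a Poisson contaminant mixed
    into a refractory train: ``C = 1 - sqrt(1 - N_v T / (N^2 (t_r - t_c)))``,
    where an out-of-range argument (more violations than a fully
    contaminated train explains) saturates at 1.
    """
    times_s = np.asarray(times_s, dtype=np.float64)
    n = times_s.size
    if n < 2:
        return 0.0
    t_r = refractory_ms / 1000.0
    t_c = censored_ms / 1000.0
    n_v = 0
    for i in range(n - 1):
        j = i + 1
        while j < n and times_s[j] - times_s[i] <= t_r:
            if times_s[j] - times_s[i] > t_c:
                n_v += 1
            j += 1
    arg = 1.0 - n_v * duration_s / (n**2 * (t_r - t_c))
    if arg < 0:
        return 1.0
    return float(np.clip(1.0 - np.sqrt(arg), 0.0, 1.0))


def type1_score(
    times_s: np.ndarray, duration_s: float, refractory_ms: float = 1.0
) -> float:
    """S_T1 = 1 - contamination; a violation-free train scores ~1."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    times_s = np.asarray(times_s, dtype=np.float64)
    if times_s.size < 2:
        return 1.0  # too few spikes to estimate contamination
    return 1.0 - contamination_llobet(times_s, duration_s, refractory_ms)


def presence_ratio(
    times_s: np.ndarray,
    duration_s: float,
    bin_s: float = 20.0,
    mean_fr_ratio: float = 0.5,
) -> float:
    """Fraction of coarse bins whose spike count exceeds half the mean count."""
    times_s = np.asarray(times_s, dtype=np.float64)
    n_bins = max(1, int(np.ceil(duration_s / bin_s)))
    counts = np.bincount(
        np.clip((times_s / bin_s).astype(np.int64), 0, n_bins - 1), minlength=n_bins
    )
    if counts.sum() == 0:
        return 0.0
    mean_count = counts.sum() / n_bins
    return float(np.mean(counts > mean_fr_ratio * mean_count))


def amplitude_cutoff(
    amplitudes: np.ndarray, n_bins: int = 32, smooth_sigma_bins: float = 1.0
) -> float:
    """Estimated missing-spike fraction from amplitude-histogram asymmetry.

    Assumes a complete cluster has a symmetric amplitude distribution: the
    mass beyond the point where the upper flank falls back to the height of
    the lowest bin estimates how much of the lower flank was cut off by the
    detection threshold. Undefined cases (histogram peak at the edge) return
    the maximal value 0.5; the result is clamped to [0, 0.5].
    """
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    if amplitudes.size < 2 or np.ptp(amplitudes) == 0:
        return 0.5
    hist, edges = np.histogram(amplitudes, bins=n_bins, density=True)
    pdf = gaussian_filter1d(hist, smooth_sigma_bins)
    peak = int(np.argmax(pdf))
    if peak == 0:
        return 0.5
    bin_width = edges[1] - edges[0]
    g = int(np.argmin(np.abs(pdf[peak:] - pdf[0]))) + peak
    fraction = float(np.sum(pdf[g:]) * bin_width)
    return float(np.clip(fraction, 0.0, 0.5))


def type2_score(
    times_s: np.ndarray,
    amplitudes: np.ndarray,
    duration_s: float,
    bin_s: float = 20.0,
    mean_fr_ratio: float = 0.5,
    n_hist_bins: int = 32,
) -> float:
    """S_T2 = presence ratio x (1 - amplitude cutoff)."""
    times_s = np.asarray(times_s, dtype=np.float64)
    if times_s.size == 0:
        return 0.0
    if times_s.size != np.asarray(amplitudes).size:
        raise ValueError("amplitudes must align with spike times")
    rp = presence_ratio(times_s, duration_s, bin_s, mean_fr_ratio)
    ac = amplitude_cutoff(amplitudes, n_hist_bins)
    return rp * (1.0 - ac)


def firing_rate_metrics(
    times_s: np.ndarray, duration_s: float, bin_s: float = 0.5
) -> tuple[float, float]:
    """Mean firing rate and the 95th-5th percentile rate range (Hz)."""
    times_s = np.asarray(times_s, dtype=np.float64)
    rf1 = times_s.size / duration_s
    n_bins = max(1, int(np.ceil(duration_s / bin_s)))
    counts = np.bincount(
        np.clip((times_s / bin_s).astype(np.int64), 0, n_bins - 1), minlength=n_bins
    )
    rates = counts / bin_s
    rf2 = float(np.percentile(rates, 95) - np.percentile(rates, 5))
    return float(rf1), rf2


def _logistic(x: float) -> float:
    # stable 1 / (1 + e^x)
    if x > 0:
        return float(np.exp(-x) / (1.0 + np.exp(-x)))
    return float(1.0 / (1.0 + np.exp(x)))


def firing_rate_score(rf1: float, rf2: float) -> float:
    """Product of logistic penalties centered at 200 Hz on rate and range."""
    if rf1 < 0 or rf2 < 0:
        raise ValueError("rates must be non-negative")
    return _logistic(rf1 - 200.0) * _logistic(rf2 - 200.0)


def snr_score(r_sn: float) -> float:
    """1 - 1/(1 + e^(SNR - 4)): 0.5 at SNR 4, ->1 for clean clusters."""
    if r_sn < 0:
        raise ValueError("SNR must be non-negative")
    return 1.0 - _logistic(r_sn - 4.0)


def compute_snr(mean_waveform: np.ndarray, noise_robust_sd: np.ndarray) -> float:
    """Peak of the mean waveform over the robust noise SD, best channel.

    ``noise_robust_sd`` is the per-channel MAD / 0.6745 (same convention as
    the noise-level estimator).
    """
    w = np.atleast_2d(np.asarray(mean_waveform, dtype=np.float64))
    sd = np.asarray(noise_robust_sd, dtype=np.float64)
    if np.any(sd <= 0):
        raise ValueError("noise level must be positive")
    return float(np.max(np.max(np.abs(w), axis=0) / sd))


@dataclass
class QualityReport:
    """Per-cluster component scores, composites and the overall sort score."""

    rows: list[dict] = field(default_factory=list)
    overall: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def composite_scores(components: list[dict[str, float]]) -> QualityReport:
    """Combine per-cluster components into composites and the overall mean.

    Each input dict must hold S_T1, S_T2, S_FR and S_SNR; the composite is
    their product and the overall score the arithmetic mean of composites.
    """
    if not components:
        warnings.warn("no clusters to score; overall score 0", stacklevel=2)
        return QualityReport(rows=[], overall=0.0)
    rows = []
    for comp in components:
        s = (
            float(comp["S_T1"])
            * float(comp["S_T2"])
            * float(comp["S_FR"])
            * float(comp["S_SNR"])
        )
        row = dict(comp)
        row["S_composite"] = float(np.clip(s, 0.0, 1.0))
        rows.append(row)
    overall = float(np.mean([r["S_composite"] for r in rows]))
    return QualityReport(rows=rows, overall=overall)


def cluster_quality(
    data: np.ndarray,
    sampling_rate: float,
    spikes: dict[int, np.ndarray],
    nt: int = 61,
) -> QualityReport:
    """Score every cluster of a sort against a recording.

    For each cluster, snippets around the spike samples give the mean
    waveform (SNR) and per-spike peak amplitudes on the best channel
    (amplitude cutoff); the recording's robust channel noise levels come
    from the chunked MAD estimator.
    """
    data = np.asarray(data, dtype=np.float64)
    duration_s = data.shape[0] / sampling_rate
    noise_sd = estimate_channel_mads(data, sampling_rate)
    nt0 = nt // 3
    components = []
    for cid in sorted(spikes):
        train = np.asarray(spikes[cid], dtype=np.int64)
        times_s = train / sampling_rate
        valid = train[(train >= nt0) & (train + (nt - nt0) <= data.shape[0])]
        if valid.size:
            snips = np.stack([data[t - nt0: t - nt0 + nt] for t in valid])
            mean_wf = snips.mean(axis=0)
            best_ch = int(np.argmax(np.max(np.abs(mean_wf), axis=0)))
            amplitudes = np.max(np.abs(snips[:, :, best_ch]), axis=1)
            r_sn = compute_snr(mean_wf, noise_sd)
        else:
            amplitudes = np.empty(0)
            r_sn = 0.0
        rf1, rf2 = firing_rate_metrics(times_s, duration_s)
        components.append(
            {
                "cluster": cid,
                "n_spikes": int(train.size),
                "R_F1": rf1,
                "R_F2": rf2,
                "R_SN": r_sn,
                "S_T1": type1_score(times_s, duration_s),
                "S_T2": type2_score(
                    times_s, amplitudes, duration_s
                ) if valid.size == train.size else type2_score(
                    valid / sampling_rate, amplitudes, duration_s
                ),
                "S_FR": firing_rate_score(rf1, rf2),
                "S_SNR": snr_score(r_sn),
            }
        )
    return composite_scores(components)
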
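"""Simple-template initialization from non-overlapping threshold crossings.

The chain mirrors the initialization of a convolutional spike sorter,
adapted for motor-unit EMG: (1) extract time-isolated waveforms from
whitened data using *multiple* single-channel thresholds and aggregate them
(one threshold misses either the small or the large units; several capture
both), scanning every ``nskip``-th batch; (2) prune inconsistent shapes —
movement artifacts and collision fragments — with HDBSCAN density-based
outlier rejection in the raw sample space; (3) take the top principal
components of the surviving waveforms as shared temporal components; (4)
K-means the waveforms and peak-normalize the cluster centers into "simple"
(universal) templates; (5) replicate each template across channels with a
Gaussian spatial envelope at several spatial sizes and detect spikes by
thresholding the matched-filter output in channel-variance units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from sklearn.cluster import HDBSCAN, KMeans
from sklearn.metrics import pairwise_distances_argmin_min

from .preprocessing import ChannelMap

__all__ = [
    "WaveformSet",
    "SimpleTemplates",
    "extract_nonoverlapping_crossings",
    "reject_outlier_waveforms",
    "compute_temporal_components",
    "make_simple_templates",
    "detect_spikes_by_convolution",
]


@dataclass
class WaveformSet:
    """Single-channel spike snippets with their provenance."""

    waveforms: np.ndarray  # (n_spikes, nt)
    channel_of_origin: np.ndarray  # (n_spikes,)
    time_of_origin: np.ndarray  # (n_spikes,) sample of the peak
    threshold_that_found_it: np.ndarray  # (n_spikes,)

    def __post_init__(self) -> None:
        keys = set(zip(self.channel_of_origin.tolist(), self.time_of_origin.tolist()))
        if len(keys) != len(self.time_of_origin):
            raise ValueError("duplicate (channel, time) entries")

    def __len__(self) -> int:
        return self.waveforms.shape[0]


@dataclass
class SimpleTemplates:
    """Peak-normalized template shapes plus shared temporal components."""

    shapes: np.ndarray  # (n_templates, nt)
    W: np.ndarray  # (n_pcs, nt), orthonormal rows

    @property
    def n_templates(self) -> int:
        return self.shapes.shape[0]

    @property
    def nt(self) -> int:
        return self.shapes.shape[1]


def _local_peaks(
    absD: np.ndarray, threshold: float, loc_time: int, loc_chan: int
) -> np.ndarray:
    """Spatiotemporal local maxima of |D| above threshold.

    A sample is a peak when it attains the maximum of its ±loc_time x
    ±loc_chan neighborhood, so one multichannel spike yields one peak.
    Returns an (n, 2) array of (time, channel).
    """
    n, c = absD.shape
    above = absD > threshold
    if not above.any():
        return np.empty((0, 2), dtype=np.int64)
    # sliding max over time then channels
    from scipy.ndimage import maximum_filter

    local_max = maximum_filter(absD, size=(2 * loc_time + 1, 2 * loc_chan + 1),
                               mode="constant")
    peaks = above & (absD >= local_max)
    t_idx, c_idx = np.nonzero(peaks)
    return np.column_stack([t_idx, c_idx])


def extract_nonoverlapping_crossings(
    D_white: np.ndarray,
    thresholds: list[float],
    sampling_rate: float,
    nt: int = 61,
    nskip: int = 2,
    batch_size: int = 60000,
    isolation_ms: float = 1.0,
    isolation_channels: int = 6,
    duplicate_ms: float = 0.2,
) -> WaveformSet:
    """Aggregate time-isolated threshold crossings across thresholds.

    Per threshold (in units of channel variance on whitened data) the
    spatiotemporal peaks of ``|D|`` are located; a peak survives only if no
    other peak lies within ±``isolation_ms`` on the same or ±6 neighboring
    channels. Only every ``nskip``-th batch is scanned. Crossings found at
    several thresholds are de-duplicated exactly by (channel, sample), and
    near-duplicates within ±``duplicate_ms`` on a channel collapse to the
    largest-amplitude instance. Waveforms are single-channel snippets with
    the peak at sample ``nt // 3``.
    """
    D = np.asarray(D_white, dtype=np.float64)
    thresholds = sorted(float(t) for t in thresholds)
    iso = int(round(isolation_ms * sampling_rate / 1000.0))
    nt0 = nt // 3
    loc_time = max(1, iso // 6)
    loc_chan = max(1, isolation_channels - 2)

    found: dict[tuple[int, int], tuple[float, float]] = {}  # (c, t) -> (amp, thr)
    n_samples = D.shape[0]
    for start in range(0, n_samples, batch_size * nskip):
        stop = min(start + batch_size, n_samples)
        absD = np.abs(D[start:stop])
        for thr in thresholds:
            peaks = _local_peaks(absD, thr, loc_time, loc_chan)
            if peaks.shape[0] == 0:
                continue
            order = np.lexsort((peaks[:, 1], peaks[:, 0]))
            peaks = peaks[order]
            times = peaks[:, 0]
            chans = peaks[:, 1]
            keep = np.ones(len(peaks), dtype=bool)
            for i in range(len(peaks)):
                lo = np.searchsorted(times, times[i] - iso, side="left")
                hi = np.searchsorted(times, times[i] + iso, side="right")
                near = np.abs(chans[lo:hi] - chans[i]) <= isolation_channels
                if np.count_nonzero(near) > 1:  # itself plus any other
                    keep[i] = False
            for t, c in peaks[keep]:
                key = (int(c), int(start + t))
                amp = float(absD[t, c])
                if key not in found or amp > found[key][0]:
                    found[key] = (amp, thr)

    # collapse near-duplicates per channel to the largest amplitude
    dup = int(round(duplicate_ms * sampling_rate / 1000.0))
    entries = sorted(found.items())  # by channel then time
    kept: list[tuple[int, int, float, float]] = []
    for (c, t), (amp, thr) in entries:
        if kept and kept[-1][0] == c and t - kept[-1][1] <= dup:
            if amp > kept[-1][2]:
                kept[-1] = (c, t, amp, thr)
        else:
            kept.append((c, t, amp, thr))

    waves, chans_o, times_o, thrs_o = [], [], [], []
    for c, t, _amp, thr in kept:
        lo = t - nt0
        if lo < 0 or lo + nt > n_samples:
            continue
        waves.append(D[lo:lo + nt, c])
        chans_o.append(c)
        times_o.append(t)
        thrs_o.append(thr)

    if not waves:
        warnings.warn("no non-overlapping threshold crossings found", stacklevel=2)
        return WaveformSet(
            waveforms=np.empty((0, nt)),
            channel_of_origin=np.empty(0, dtype=np.int64),
            time_of_origin=np.empty(0, dtype=np.int64),
            threshold_that_found_it=np.empty(0),
        )
    return WaveformSet(
        waveforms=np.asarray(waves),
        channel_of_origin=np.asarray(chans_o, dtype=np.int64),
        time_of_origin=np.asarray(times_o, dtype=np.int64),
        threshold_that_found_it=np.asarray(thrs_o),
    )


def reject_outlier_waveforms(
    wset: WaveformSet, min_cluster_size: int = 20
) -> WaveformSet:
    """Drop waveforms HDBSCAN labels as noise (low-density outliers).

    Clustering runs on the raw sample vectors (Euclidean, full feature
    space). With fewer waveforms than ``min_cluster_size`` the input is
    returned unchanged with a warning. Output is always a subset of the
    input, in the original order.
    """
    if len(wset) == 0:
        raise ValueError("empty waveform set")
    if len(wset) < min_cluster_size:
        warnings.warn(
            f"only {len(wset)} waveforms (< min_cluster_size={min_cluster_size}); "
            "skipping outlier rejection",
            stacklevel=2,
        )
        return wset
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(
        wset.waveforms
    )
    mask = labels != -1
    if not mask.any():
        warnings.warn("HDBSCAN labeled everything noise; keeping input", stacklevel=2)
        return wset
    return WaveformSet(
        waveforms=wset.waveforms[mask],
        channel_of_origin=wset.channel_of_origin[mask],
        time_of_origin=wset.time_of_origin[mask],
        threshold_that_found_it=wset.threshold_that_found_it[mask],
    )


def compute_temporal_components(waveforms: np.ndarray, n_pcs: int = 9) -> np.ndarray:
    """Top principal axes of the waveform matrix, orthonormal rows.

    Computed by SVD of the (uncentered) waveform matrix, ordered by
    explained variance. A rank deficit is padded with an orthonormal
    complement and a warning.
    """
    X = np.asarray(waveforms, dtype=np.float64)
    if X.shape[0] < n_pcs:
        raise ValueError(f"need at least {n_pcs} waveforms, got {X.shape[0]}")
    _, s, vt = np.linalg.svd(X, full_matrices=True)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if rank < n_pcs:
        warnings.warn(
            f"waveform matrix rank {rank} < n_pcs {n_pcs}; padding with "
            "orthogonal complement",
            stacklevel=2,
        )
    return vt[:n_pcs]


def make_simple_templates(
    wset: WaveformSet, n_templates: int = 9, n_pcs: int = 9, seed: int = 0
) -> SimpleTemplates:
    """K-means the waveforms; peak-normalized cluster centers are templates."""
    X = wset.waveforms
    if X.shape[0] < n_templates:
        raise ValueError(f"need at least {n_templates} waveforms, got {X.shape[0]}")
    km = KMeans(n_clusters=n_templates, n_init=10, random_state=seed).fit(X)
    centers = km.cluster_centers_.copy()
    # guard: re-seed any empty cluster at the farthest point
    counts = np.bincount(km.labels_, minlength=n_templates)
    for k in np.nonzero(counts == 0)[0]:
        _, dist = pairwise_distances_argmin_min(X, centers)
        centers[k] = X[int(np.argmax(dist))]
    peaks = np.max(np.abs(centers), axis=1, keepdims=True)
    peaks[peaks == 0] = 1.0
    shapes = centers / peaks
    W = compute_temporal_components(X, n_pcs=min(n_pcs, X.shape[0]))
    return SimpleTemplates(shapes=shapes, W=W)


def detect_spikes_by_convolution(
    D_white: np.ndarray,
    templates: SimpleTemplates,
    channel_map: ChannelMap,
    Th_universal: float = 9.0,
    min_template_size: float = 10.0,
    template_sizes: int = 5,
    nearest_chans: int = 10,
) -> pd.DataFrame:
    """Reference convolutional detector over spatially replicated templates.

    Each template shape is replicated across channels with a Gaussian
    spatial envelope whose standard deviation runs over ``1..template_sizes``
    multiples of ``min_template_size`` (micrometers on the channel map).
    Envelope and shape are unit-normalized so matched-filter outputs on
    whitened data are in channel-variance units; detections are score
    maxima above ``Th_universal`` that survive non-maximum suppression over
    ±half a window in time and ``nearest_chans`` channels. The best size per
    detection is retained.

    Returns a DataFrame with columns time, channel, template, size, score.
    """
    D = np.asarray(D_white, dtype=np.float64)
    n_samples, n_ch = D.shape
    if channel_map.positions.shape[0] != n_ch:
        raise ValueError("channel map size mismatches data")
    nt = templates.nt
    nt0 = nt // 3
    shapes = templates.shapes / np.linalg.norm(templates.shapes, axis=1, keepdims=True)

    pos = channel_map.positions
    best_score = np.zeros((n_samples, n_ch))
    best_template = np.full((n_samples, n_ch), -1, dtype=np.int64)
    best_size = np.zeros((n_samples, n_ch))
    for m in range(1, template_sizes + 1):
        sd = m * min_template_size
        env = np.exp(-0.5 * ((pos[None, :] - pos[:, None]) / sd) ** 2)
        # limit each envelope to its nearest channels, unit L2 norm
        for c in range(n_ch):
            order = np.argsort(np.abs(pos - pos[c]), kind="stable")
            env[c, order[nearest_chans:]] = 0.0
        env /= np.linalg.norm(env, axis=1, keepdims=True)
        proj = D @ env.T  # (time, center channel)
        for k, shape in enumerate(shapes):
            # score[t] = sum_tau proj[t - nt0 + tau] * shape[tau]
            full = fftconvolve(proj, shape[::-1][:, None], mode="full", axes=0)
            score = full[nt - 1 - nt0: nt - 1 - nt0 + n_samples]
            better = np.abs(score) > best_score
            best_score[better] = np.abs(score)[better]
            best_template[better] = k
            best_size[better] = sd

    t_idx, c_idx = np.nonzero(best_score > Th_universal)
    if t_idx.size == 0:
        return pd.DataFrame(columns=["time", "channel", "template", "size", "score"])
    scores = best_score[t_idx, c_idx]
    order = np.argsort(-scores, kind="stable")
    accepted: list[int] = []
    acc_t: list[int] = []
    acc_c: list[int] = []
    for i in order:
        t, c = t_idx[i], c_idx[i]
        clash = any(
            abs(t - ta) <= nt // 2 and abs(c - ca) < nearest_chans
            for ta, ca in zip(acc_t, acc_c)
        )
        if not clash:
            accepted.append(i)
            acc_t.append(t)
            acc_c.append(c)
    accepted = sorted(accepted, key=lambda i: t_idx[i])
    return pd.DataFrame(
        {
            "time": t_idx[accepted],
            "channel": c_idx[accepted],
            "template": best_template[t_idx[accepted], c_idx[accepted]],
            "size": best_size[t_idx[accepted], c_idx[accepted]],
            "score": best_score[t_idx[accepted], c_idx[accepted]],
        }
    )
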
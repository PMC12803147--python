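"""Motor-unit recruitment model: ground-truth spike trains from a drive signal.

The model follows the size-principle picture of motor-pool recruitment.
Each unit draws an activation threshold from a shifted exponential,
``U1 = theta1 * Exp(lambda=1) + theta2``, so a few units are recruited early
and progressively fewer at higher drive. Given a force (or kinematic) signal
``F``, a unit may fire at sample ``t`` only while ``F[t]`` exceeds its
time-varying threshold, and then does so with per-sample probability
``sigmoid(F[t] - U1[u, t])`` (a Bernoulli draw). Every spike adds a
spike-history kernel to that unit's threshold trace over the following
``len(K)`` samples; the kernel's initial plateau is large enough to gate the
unit off completely, enforcing an absolute refractory period and bounding the
attainable firing rate.

Units evolve independently; time is strictly sequential within a unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import butter, sosfiltfilt

from ._rng import substream

__all__ = [
    "MotorPool",
    "ForceSignal",
    "SpikeTrains",
    "sample_thresholds",
    "make_history_kernel",
    "make_force_signal",
    "generate_spike_trains",
    "empirical_firing_rates",
]


def sample_thresholds(
    n_units: int, theta1: float, theta2: float, seed: int
) -> np.ndarray:
    """Draw per-unit activation thresholds ``theta1 * Exp(1) + theta2``.

    The exponential rate is fixed at lambda = 1; ``theta1`` scales the spread
    and ``theta2`` offsets the floor. Deterministic under ``seed``.
    """
    if theta1 < 0:
        raise ValueError("theta1 must be non-negative")
    if n_units <= 0:
        raise ValueError("n_units must be positive")
    rng = substream(seed, "unit-thresholds")
    return theta1 * rng.exponential(1.0, size=n_units) + theta2


def make_history_kernel(
    abs_refractory_ms: float,
    decay_tau_ms: float,
    amplitude: float,
    sampling_rate: float,
) -> np.ndarray:
    """Additive post-spike threshold increment.

    Rectangular plateau of height ``amplitude`` spanning the absolute
    refractory period, followed by an exponential tail ``amplitude *
    exp(-t/tau)`` truncated where it falls below 1% of the amplitude. The
    plateau makes refractory violations impossible when the amplitude exceeds
    the drive's dynamic range; the tail shapes the relative refractory period
    and thereby the attainable firing rate.
    """
    if abs_refractory_ms <= 0:
        raise ValueError("abs_refractory_ms must be positive")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    n_abs = max(1, round(abs_refractory_ms * sampling_rate / 1000.0))
    tau_samples = decay_tau_ms * sampling_rate / 1000.0
    if tau_samples <= 0:
        return np.full(n_abs, amplitude)
    # tail kept while amplitude * exp(-k/tau) > 0.01 * amplitude
    n_tail = int(np.floor(tau_samples * np.log(100.0)))
    k = np.arange(n_tail + 1, dtype=np.float64)
    tail = amplitude * np.exp(-k / tau_samples)
    tail = tail[tail > 0.01 * amplitude]
    return np.concatenate([np.full(n_abs, amplitude), tail[1:]])


@dataclass
class ForceSignal:
    """Drive signal in arbitrary force units."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("force signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("force signal must be finite")


def make_force_signal(
    duration_s: float,
    sampling_rate: float = 30000.0,
    seed: int = 0,
    *,
    burst_rate_hz: float = 2.0,
    noise_cutoff_hz: float = 5.0,
    amplitude: float = 1.0,
    noise_level: float = 0.3,
) -> ForceSignal:
    """Synthetic locomotor-like drive: periodic bursts plus slow noise.

    Emulates the envelope of muscle drive during rhythmic behavior (e.g.
    step cycles at ``burst_rate_hz``): half-wave-rectified sinusoidal bursts
    with low-pass-filtered, rectified Gaussian fluctuations superimposed.
    """
    n = int(round(duration_s * sampling_rate))
    if n < 1:
        raise ValueError("duration too short")
    t = np.arange(n) / sampling_rate
    bursts = amplitude * np.clip(np.sin(2 * np.pi * burst_rate_hz * t), 0.0, None)
    rng = substream(seed, "force-noise")
    white = rng.normal(0.0, 1.0, size=n)
    sos = butter(2, noise_cutoff_hz, btype="low", fs=sampling_rate, output="sos")
    slow = sosfiltfilt(sos, white)
    sd = np.std(slow)
    if sd > 0:
        slow = slow / sd
    drive = np.clip(bursts + noise_level * amplitude * slow, 0.0, None)
    return ForceSignal(samples=drive, sampling_rate=sampling_rate)


@dataclass
class MotorPool:
    """A pool of motor units with exponentially distributed thresholds."""

    n_units: int
    theta1: float
    theta2: float
    sampling_rate: float
    seed: int
    abs_refractory_ms: float = 1.0
    decay_tau_ms: float = 5.0
    kernel_amplitude: float | None = None  # None -> 10 x drive dynamic range
    thresholds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.thresholds = sample_thresholds(
            self.n_units, self.theta1, self.theta2, self.seed
        )

    def history_kernel(self, force: ForceSignal) -> np.ndarray:
        amp = self.kernel_amplitude
        if amp is None:
            span = float(np.max(force.samples) - np.min(self.thresholds))
            amp = 10.0 * max(span, 1.0)
        return make_history_kernel(
            self.abs_refractory_ms, self.decay_tau_ms, amp, self.sampling_rate
        )


@dataclass
class SpikeTrains:
    """Per-unit sorted spike sample indices with the recording duration."""

    trains: list[np.ndarray]
    duration: int
    sampling_rate: float

    def __post_init__(self) -> None:
        for i, tr in enumerate(self.trains):
            tr = np.asarray(tr, dtype=np.int64)
            if tr.size and (np.any(np.diff(tr) <= 0) or tr[0] < 0 or tr[-1] >= self.duration):
                raise ValueError(f"unit {i}: spike indices must be strictly "
                                 "increasing and within [0, duration)")
            self.trains[i] = tr

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains])


@njit(cache=False)
def _unit_loop(force, thresh0, kernel, uniforms, spikes_out):  # pragma: no cover
    n_spikes = 0
    lk = kernel.shape[0]
    extra = np.zeros(force.shape[0] + lk)
    for t in range(force.shape[0]):
        u1 = thresh0 + extra[t]
        if force[t] > u1:
            p = 1.0 / (1.0 + np.exp(-(force[t] - u1)))
            if uniforms[t] < p:
                spikes_out[n_spikes] = t
                n_spikes += 1
                for k in range(lk):
                    extra[t + k] += kernel[k]
    return n_spikes


def generate_spike_trains(pool: MotorPool, force: ForceSignal) -> SpikeTrains:
    """Run the recruitment model; returns ground-truth spike trains.

    Deterministic under the pool seed: each unit consumes a dedicated
    substream of pre-drawn uniforms, so adding units leaves the others'
    trains untouched.
    """
    if pool.sampling_rate != force.sampling_rate:
        raise ValueError("pool and force sampling rates differ")
    f = force.samples
    kernel = pool.history_kernel(force)
    trains: list[np.ndarray] = []
    scratch = np.empty(f.shape[0], dtype=np.int64)
    for u in range(pool.n_units):
        uniforms = substream(pool.seed, f"binomial-unit-{u}").random(f.shape[0])
        n = _unit_loop(f, float(pool.thresholds[u]), kernel, uniforms, scratch)
        trains.append(scratch[:n].copy())
    return SpikeTrains(trains=trains, duration=f.shape[0], sampling_rate=pool.sampling_rate)


def empirical_firing_rates(trains: SpikeTrains) -> np.ndarray:
    """Mean firing rate per unit in Hz, for checking a configuration."""
    dur_s = trains.duration / trains.sampling_rate
    return trains.counts() / dur_s
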
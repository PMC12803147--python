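"""Template bases: the generative dictionary for multichannel MUAP waveforms.

A :class:`TemplateBasis` holds the low-rank spatiotemporal decomposition used
to synthesize motor-unit action potentials: orthonormal temporal components
``W`` (principal axes over the spike window), per-unit channel weights ``U0``
(PC loadings per channel), an inverse whitening matrix to map back to raw
channel space, and a bits-to-voltage scale ``b``.

Bases can be extracted from a previously sorted recording, or generated
synthetically by :func:`make_synthetic_basis`, which emulates the empirical
properties of intramuscular MUAPs: multiphasic shapes, conduction delays of
up to a few milliseconds across channels, and amplitude decay with distance
from a dominant channel.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rng import substream

__all__ = ["TemplateBasis", "make_synthetic_basis", "save_basis", "load_basis"]

_ORTHO_TOL = 1e-8


@dataclass
class TemplateBasis:
    """Low-rank generative basis for per-unit multichannel MUAP templates.

    Attributes
    ----------
    W : (n_pcs, nt) array
        Temporal components; rows are orthonormal.
    U0 : (n_units, n_channels, n_pcs) array
        Per-unit channel weights (PC loadings).
    w_inv : (n_channels, n_channels) array
        Inverse whitening matrix applied across channels on reconstruction.
    b : float
        Positive bits-to-voltage conversion scale.
    sampling_rate : float
        Hz.
    """

    W: np.ndarray
    U0: np.ndarray
    w_inv: np.ndarray
    b: float = 1.0
    sampling_rate: float = 30000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.U0 = np.asarray(self.U0, dtype=np.float64)
        self.w_inv = np.asarray(self.w_inv, dtype=np.float64)
        self.validate()

    # -- derived sizes -----------------------------------------------------
    @property
    def n_pcs(self) -> int:
        return self.W.shape[0]

    @property
    def nt(self) -> int:
        return self.W.shape[1]

    @property
    def n_units(self) -> int:
        return self.U0.shape[0]

    @property
    def n_channels(self) -> int:
        return self.U0.shape[1]

    def validate(self) -> None:
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D [n_pcs x nt]")
        if self.U0.ndim != 3:
            raise ValueError("U0 must be 3-D [n_units x n_channels x n_pcs]")
        if self.nt < 3:
            raise ValueError("nt must be >= 3")
        if self.n_pcs > self.nt:
            raise ValueError("n_pcs cannot exceed nt")
        if self.U0.shape[2] != self.n_pcs:
            raise ValueError(
                f"U0 trailing dimension {self.U0.shape[2]} != n_pcs {self.n_pcs}"
            )
        if self.w_inv.shape != (self.n_channels, self.n_channels):
            raise ValueError(
                f"w_inv shape {self.w_inv.shape} inconsistent with "
                f"n_channels {self.n_channels}"
            )
        if not self.b > 0:
            raise ValueError("b must be positive")
        gram = self.W @ self.W.T
        if not np.allclose(gram, np.eye(self.n_pcs), atol=1e-6):
            raise ValueError("W rows are not orthonormal")
        if not np.all(np.isfinite(self.U0)) or not np.all(np.isfinite(self.w_inv)):
            raise ValueError("basis arrays must be finite")

    def template(self, unit: int) -> np.ndarray:
        """Reconstructed noiseless template of one unit, shape (nt, n_channels)."""
        raw = self.b * (self.U0[unit] @ self.W)  # (channels, nt)
        return raw.T @ self.w_inv


def _gabor_waveform(rng: np.random.Generator, nt: int, center: int) -> np.ndarray:
    """Sum of 2-3 Gaussian-windowed sinusoids: a multiphasic MUAP-like shape."""
    t = np.arange(nt, dtype=np.float64)
    n_atoms = int(rng.integers(2, 4))
    wave = np.zeros(nt)
    for _ in range(n_atoms):
        mu = center + rng.normal(0.0, nt / 12.0)
        sigma = rng.uniform(nt / 16.0, nt / 7.0)
        freq = rng.uniform(1.0, 2.5) / sigma  # 1-2.5 cycles per envelope width
        phase = rng.uniform(0.0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        wave += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2) * np.sin(
            2 * np.pi * freq * (t - mu) + phase
        )
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


def _shift_zero_fill(x: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(x)
    if k == 0:
        out[:] = x
    elif k > 0:
        out[k:] = x[:-k]
    else:
        out[:k] = x[-k:]
    return out


def _sign_changes(x: np.ndarray) -> int:
    s = np.sign(x[np.abs(x) > 1e-3 * np.max(np.abs(x))])
    return int(np.count_nonzero(np.diff(s) != 0))


def make_synthetic_basis(
    n_units: int,
    n_channels: int,
    nt: int = 61,
    n_pcs: int = 9,
    max_delay: int = 10,
    seed: int = 0,
    *,
    b: float = 1.0,
    sampling_rate: float = 30000.0,
    whiten: bool = False,
    amplitude_range: tuple[float, float] = (0.5, 2.0),
) -> TemplateBasis:
    """Generate a synthetic template basis with realistic MUAP structure.

    Each unit gets a multiphasic dominant-channel waveform (a sum of 2-3
    Gaussian-windowed sinusoids), propagated to other channels with integer
    sample delays up to ``±max_delay`` and exponentially decaying amplitude.
    ``W`` is then the PCA basis of the generated waveform collection and
    ``U0`` its least-squares loadings, so the basis is internally consistent.

    Pure function of its arguments: identical calls give identical bases.
    """
    if n_units <= 0 or n_channels <= 0 or nt < 3 or n_pcs <= 0:
        raise ValueError("counts must be positive and nt >= 3")
    if n_pcs > nt:
        raise ValueError("n_pcs cannot exceed nt")
    if max_delay > nt // 2:
        raise ValueError("max_delay cannot exceed nt/2")

    rng = substream(seed, "synthetic-basis")
    center = nt // 3  # peak lands at the conventional alignment sample
    # muscle fibers share a propagation direction, so all units get a common
    # conduction-delay gradient (samples per channel) with mild unit-to-unit
    # jitter; this is what makes a single per-channel delay correction useful
    shared_slope = rng.uniform(-1.0, 1.0) * max_delay / max(1, n_channels - 1)
    templates = np.zeros((n_units, nt, n_channels))
    for u in range(n_units):
        for _attempt in range(100):
            wave = _gabor_waveform(rng, nt, center)
            if _sign_changes(wave) >= 2:
                break
        dom = int(rng.integers(0, n_channels))
        amp = rng.uniform(*amplitude_range)
        decay_scale = rng.uniform(1.0, max(1.5, n_channels / 3.0))
        slope = shared_slope * rng.uniform(0.8, 1.2)
        for c in range(n_channels):
            dist = c - dom
            delay = int(np.clip(round(slope * dist), -max_delay, max_delay))
            gain = amp * np.exp(-abs(dist) / decay_scale)
            templates[u, :, c] = gain * _shift_zero_fill(wave, delay)

    # PCA of all per-channel waveforms -> orthonormal temporal components
    rows = templates.transpose(0, 2, 1).reshape(-1, nt)
    rows_c = rows - rows.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(rows_c, full_matrices=True)
    W = vt[:n_pcs]

    # least-squares channel weights (orthonormal rows -> projection)
    U0 = np.einsum("utc,pt->ucp", templates, W) / b

    if whiten:
        # random SPD inverse-whitening matrix to exercise the un-whitening path
        A = rng.normal(0.0, 1.0, size=(n_channels, n_channels))
        w_inv = A @ A.T / n_channels + np.eye(n_channels)
    else:
        w_inv = np.eye(n_channels)

    meta = {"seed": int(seed), "max_delay": int(max_delay), "synthetic": True}
    return TemplateBasis(W=W, U0=U0, w_inv=w_inv, b=b, sampling_rate=sampling_rate, meta=meta)


def save_basis(basis: TemplateBasis, path: str | Path) -> None:
    """Write a basis to an NPZ archive with a JSON metadata member."""
    path = Path(path)
    header = {
        "n_units": basis.n_units,
        "n_channels": basis.n_channels,
        "nt": basis.nt,
        "n_pcs": basis.n_pcs,
        "b": basis.b,
        "sampling_rate": basis.sampling_rate,
        **basis.meta,
    }
    buf = io.BytesIO()
    np.savez(buf, W=basis.W, U0=basis.U0, w_inv=basis.w_inv)
    buf.seek(0)
    with zipfile.ZipFile(buf, "a") as zf:
        zf.writestr("meta.json", json.dumps(header))
    path.write_bytes(buf.getvalue())


def load_basis(path: str | Path) -> TemplateBasis:
    """Load a basis written by :func:`save_basis`; validates all invariants."""
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        for required in ("W.npy", "U0.npy", "w_inv.npy", "meta.json"):
            if required not in names:
                raise ValueError(f"basis file missing member: {required}")
        meta = json.loads(zf.read("meta.json"))
    arrays = np.load(path)
    for key in ("b", "sampling_rate"):
        if key not in meta:
            raise ValueError(f"basis metadata missing field: {key}")
    extra = {
        k: v
        for k, v in meta.items()
        if k not in {"n_units", "n_channels", "nt", "n_pcs", "b", "sampling_rate"}
    }
    basis = TemplateBasis(
        W=arrays["W"],
        U0=arrays["U0"],
        w_inv=arrays["w_inv"],
        b=float(meta["b"]),
        sampling_rate=float(meta["sampling_rate"]),
        meta=extra,
    )
    for key, attr in (("n_units", "n_units"), ("n_channels", "n_channels"),
                      ("nt", "nt"), ("n_pcs", "n_pcs")):
        if key in meta and int(meta[key]) != getattr(basis, attr):
            raise ValueError(f"declared {key}={meta[key]} mismatches arrays")
    return basis
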
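"""Reading and writing the on-disk formats.

Recordings travel as flat little-endian int16 binary (time-major,
channel-interleaved) with a JSON sidecar describing the geometry and the
int16-to-microvolt scale. Ground truth is a two-column CSV
(``unit_id,sample_index``, 0-based samples). Sorter output is accepted
either as a Phy-style directory (``spike_times.npy`` int64 samples plus
``spike_clusters.npy`` int32 labels) or as a ``cluster_id,sample_index``
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recruitment import SpikeTrains
from .waveforms import SimulatedRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_ground_truth",
    "load_ground_truth",
    "read_sorter_output",
    "write_phy_output",
]


def save_recording(rec: SimulatedRecording, prefix: str | Path) -> None:
    """Write ``<prefix>.bin`` + ``<prefix>.json`` and the ground-truth CSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    peak = float(np.max(np.abs(rec.data))) if rec.data.size else 0.0
    scale = peak / 32000.0 if peak > 0 else 1.0
    raw = np.round(rec.data / scale).astype("<i2")
    raw.tofile(prefix.with_suffix(".bin"))
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "n_channels": rec.n_channels,
        "dtype": "int16",
        "scale_to_uV": scale,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    save_ground_truth(rec.ground_truth, prefix.parent / (prefix.name + "_ground_truth.csv"))


def load_recording(prefix: str | Path) -> tuple[np.ndarray, float]:
    """Load a flat binary recording; returns (data [time x channels], fs)."""
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    n_ch = int(sidecar["n_channels"])
    raw = np.fromfile(prefix.with_suffix(".bin"), dtype="<i2").reshape(-1, n_ch)
    return raw.astype(np.float64) * float(sidecar["scale_to_uV"]), float(
        sidecar["sampling_rate"]
    )


def save_ground_truth(trains: SpikeTrains, path: str | Path) -> None:
    rows = [
        {"unit_id": u, "sample_index": int(t)}
        for u, train in enumerate(trains.trains)
        for t in train
    ]
    pd.DataFrame(rows, columns=["unit_id", "sample_index"]).to_csv(path, index=False)


def load_ground_truth(path: str | Path, duration: int | None = None) -> SpikeTrains:
    df = pd.read_csv(path)
    if not {"unit_id", "sample_index"} <= set(df.columns):
        raise ValueError("ground-truth CSV must have unit_id,sample_index columns")
    units = sorted(df["unit_id"].unique())
    trains = [
        np.sort(df.loc[df["unit_id"] == u, "sample_index"].to_numpy(np.int64))
        for u in units
    ]
    if duration is None:
        duration = int(max((t[-1] for t in trains if t.size), default=0)) + 1
    return SpikeTrains(trains=trains, duration=duration, sampling_rate=1.0)


def read_sorter_output(path: str | Path) -> dict[int, np.ndarray]:
    """Read sorted spike trains as {cluster_id: sorted sample indices}.

    ``path`` may be a Phy-style directory or a CSV file.
    """
    path = Path(path)
    if path.is_dir():
        times = np.load(path / "spike_times.npy").ravel().astype(np.int64)
        clusters = np.load(path / "spike_clusters.npy").ravel().astype(np.int64)
    else:
        df = pd.read_csv(path)
        if not {"cluster_id", "sample_index"} <= set(df.columns):
            raise ValueError("sorter CSV must have cluster_id,sample_index columns")
        times = df["sample_index"].to_numpy(np.int64)
        clusters = df["cluster_id"].to_numpy(np.int64)
    return {
        int(c): np.sort(times[clusters == c]) for c in np.unique(clusters)
    }


def write_phy_output(
    path: str | Path, spikes: dict[int, np.ndarray]
) -> None:
    """Write a minimal Phy-style directory from {cluster: sample indices}."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    all_times = np.concatenate([np.asarray(v, np.int64) for v in spikes.values()])
    all_clust = np.concatenate(
        [np.full(len(v), c, dtype=np.int32) for c, v in spikes.items()]
    )
    order = np.argsort(all_times, kind="stable")
    np.save(path / "spike_times.npy", all_times[order])
    np.save(path / "spike_clusters.npy", all_clust[order])
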
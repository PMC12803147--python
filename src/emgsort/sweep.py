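"""Run configuration, parameter-sweep expansion, run records and ranking.

The YAML configuration mirrors the tool's five sections (data, sorting,
group, algorithm/KS, misc). Sweeps expand a mapping of parameter-name to
value-list into concrete combinations; *linked* parameter groups (e.g. the
pair of universal/learned similarity thresholds) advance their indices
together instead of entering the Cartesian product, which lets a user state
explicit combinations. Finished runs archive their configuration with
appended result fields, and the overall composite score is embedded in the
output folder name so runs can be ranked at a glance.
"""

from __future__ import annotations

import itertools
import time
import warnings
from pathlib import Path

import yaml

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "validate_config",
    "expand_sweep",
    "run_record",
    "rank_runs",
    "SCORE_TAG",
]

SCORE_TAG = ".score_"

_RECOGNIZED_DATASET_TYPES = {"binary", "openephys", "nwb", "blackrock", "intan"}


def default_config() -> dict:
    """Template configuration with the tool's default parameter values."""
    return {
        "data": {
            "dataset_type": "binary",
            "emg_passband": [250, 5000],
            "time_range": [0, 0],
            "emg_recordings": [0],
            "binary_sampling_rate": None,
            "binary_num_channels": None,
        },
        "sorting": {
            "output_folder": None,
            "do_param_sweep": False,
            "params_to_sweep": {},
            "linked_params_for_sweep": [["Th_universal", "Th_learned"]],
        },
        "group": {
            "emg_chan_list": ["all"],
            "remove_bad_emg_chans": False,
        },
        "algorithm": {
            "Th_single_ch": [6, 9, 12, 15],
            "Th_universal": 9,
            "Th_learned": 8,
            "nt": 61,
            "nskip": 2,
            "n_pcs": 9,
            "n_templates": 9,
            "batch_size": 60000,
            "whitening_range": 32,
            "min_template_size": 10,
            "template_sizes": 5,
            "nearest_chans": 10,
            "remove_chan_delays": True,
            "remove_spike_outliers": True,
            "hdbscan_min_cluster_size": 20,
            "seed": 0,
        },
    }


def validate_config(cfg: dict) -> dict:
    dtype = cfg.get("data", {}).get("dataset_type", "binary")
    if dtype not in _RECOGNIZED_DATASET_TYPES:
        raise ValueError(f"unknown dataset_type {dtype!r}")
    if dtype != "binary":
        raise ValueError(
            f"dataset_type {dtype!r} is recognized but not supported; "
            "convert to flat binary + JSON sidecar"
        )
    alg = cfg.get("algorithm", {})
    for key in ("Th_universal", "Th_learned"):
        if key in alg and alg[key] is not None and alg[key] <= 0:
            raise ValueError(f"{key} must be positive")
    thr = alg.get("Th_single_ch", [])
    if any(t <= 0 for t in (thr if isinstance(thr, list) else [thr])):
        raise ValueError("Th_single_ch thresholds must be positive")
    sweep = cfg.get("sorting", {})
    swept = sweep.get("params_to_sweep", {}) or {}
    for group in sweep.get("linked_params_for_sweep", []) or []:
        lengths = {len(swept[name]) for name in group if name in swept}
        if len(lengths) > 1:
            raise ValueError(f"linked parameters {group} have unequal lengths")
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def expand_sweep(
    swept: dict[str, list], linked: list[list[str]] | None = None
) -> list[dict]:
    """Expand swept parameter lists into concrete combinations.

    Unlinked parameters combine by Cartesian product in the order given;
    parameters in a linked group advance their indices together (their
    lists must be equally long). Deterministic order.
    """
    linked = linked or []
    linked_active = []
    for group in linked:
        present = [n for n in group if n in swept]
        if len(present) >= 2:
            lengths = {len(swept[n]) for n in present}
            if len(lengths) != 1:
                raise ValueError(f"linked parameters {present} have unequal lengths")
            linked_active.append(present)

    axes: list[list[dict]] = []
    consumed: set[str] = set()
    for name in swept:
        if name in consumed:
            continue
        group = next((g for g in linked_active if name in g), None)
        if group is not None:
            axes.append(
                [
                    {n: swept[n][i] for n in group}
                    for i in range(len(swept[group[0]]))
                ]
            )
            consumed.update(group)
        else:
            axes.append([{name: v} for v in swept[name]])
            consumed.add(name)

    combos = []
    for parts in itertools.product(*axes):
        combo: dict = {}
        for part in parts:
            combo.update(part)
        combos.append(combo)
    return combos


def run_record(cfg: dict, results: dict, folder: str | Path) -> Path:
    """Archive the configuration + result fields; tag folder with the score.

    Writes ``run_config.yaml`` (config snapshot with a ``results`` section
    appended) into ``folder`` and renames the folder with a
    ``.score_<overall to 4 decimals>`` suffix. Returns the final path.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    snapshot = dict(cfg)
    snapshot["results"] = results
    save_config(snapshot, folder / "run_config.yaml")
    overall = results.get("overall_score")
    if overall is None:
        return folder
    name = folder.name.split(SCORE_TAG)[0]
    target = folder.with_name(f"{name}{SCORE_TAG}{overall:.4f}")
    if target != folder:
        folder.rename(target)
    return target


def _folder_score(folder: Path) -> float | None:
    if SCORE_TAG in folder.name:
        try:
            return float(folder.name.split(SCORE_TAG)[-1])
        except ValueError:
            pass
    record = folder / "run_config.yaml"
    if record.exists():
        with open(record) as fh:
            snap = yaml.safe_load(fh)
        score = (snap or {}).get("results", {}).get("overall_score")
        if score is not None:
            return float(score)
    return None


def rank_runs(parent: str | Path) -> list[tuple[Path, float | None]]:
    """Order run folders by overall composite score, descending.

    Ties keep insertion (timestamp) order; folders with no score rank last
    with a warning.
    """
    parent = Path(parent)
    folders = sorted(
        (f for f in parent.iterdir() if f.is_dir()),
        key=lambda f: f.stat().st_mtime,
    )
    scored, unscored = [], []
    for f in folders:
        s = _folder_score(f)
        if s is None:
            warnings.warn(f"run folder {f.name} has no score; ranked last", stacklevel=2)
            unscored.append((f, None))
        else:
            scored.append((f, s))
    scored.sort(key=lambda x: -x[1])  # stable: ties keep mtime order
    return scored + unscored


def timestamp_folder(parent: str | Path, prefix: str = "sort") -> Path:
    """A fresh uniquely named run folder under ``parent``."""
    parent = Path(parent)
    parent.mkdir(parents=True, exist_ok=True)
    stamp = time.strftime("%Y%m%d_%H%M%S")
    i = 0
    while True:
        cand = parent / (f"{prefix}_{stamp}" + (f"_{i}" if i else ""))
        if not cand.exists():
            return cand
        i += 1
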
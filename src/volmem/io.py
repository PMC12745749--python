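"""CSV schemas and JSON run configuration.

All tables are UTF-8 CSV with a header row, "." decimal, metres and
degrees as stated per column, and empty fields for missing values.
Write-then-read round-trips values exactly (shortest-repr floats).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RunConfig",
    "load_config",
    "TRIAL_COLUMNS",
    "TRAJECTORY_COLUMNS",
    "read_trials",
    "write_trials",
    "read_targets",
    "write_targets",
    "read_trajectories",
    "write_trajectories",
]

TRIAL_COLUMNS = [
    "participant", "group", "locomotion", "deform_type", "phase", "trial",
    "block", "environment", "target",
    "start_x", "start_y", "start_z", "resp_x", "resp_y", "resp_z",
]

TRAJECTORY_COLUMNS = ["trial_id", "t", "x", "y", "z", "azimuth", "elevation"]


@dataclass
class RunConfig:
    """Pipeline settings; everything stochastic keys off ``seed``."""

    seed: int = 0
    base_length: float = 3.0
    stretch: float = 1.33
    compress: float = 0.67
    resolution: int = 25
    c: float = 1.5
    models: list = field(default_factory=lambda: [
        "fixed_distance", "fixed_ratio", "boundary_proximity", "ground_proximity"])
    n_per_group: int = 20
    renormalize: bool = False
    out_dir: str = "volmem_out"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def load_config(path=None, **overrides) -> RunConfig:
    """Load a JSON config file; unknown keys raise, overrides win."""
    data = {}
    if path is not None:
        data = json.loads(Path(path).read_text())
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["participant", "phase", "environment", "target",
                          "resp_x", "resp_y", "resp_z"], "trial table")
    return df


def write_targets(targets: dict, path) -> None:
    rows = [{"target": k, "x": v[0], "y": v[1], "z": v[2]}
            for k, v in targets.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_targets(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    _require_columns(df, ["target", "x", "y", "z"], "target table")
    return {str(r["target"]): np.array([r["x"], r["y"], r["z"]], float)
            for _, r in df.iterrows()}


def write_trajectories(trajectories: dict, path) -> None:
    """Concatenate per-trial trajectory tables into one long CSV."""
    if trajectories:
        pd.concat(trajectories.values(), ignore_index=True).to_csv(path, index=False)
    else:
        pd.DataFrame(columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def read_trajectories(path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path)
    _require_columns(df, TRAJECTORY_COLUMNS, "trajectory table")
    return {str(tid): sub.reset_index(drop=True)
            for tid, sub in df.groupby("trial_id", sort=True)}
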
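"""Trajectory-derived navigation measures.

Trajectories are tables of 40 Hz samples (t, x, y, z, azimuth, elevation)
per trial.  Four per-participant measures characterise navigation style:

* state occupancy — number of distinct bins of a 50x50x50 grid visited
  across a participant's trials (exploration extent);
* path length — cumulative frame-wise 3D Euclidean distance per trial;
* path dissimilarity — dynamic time warping (DTW) distance between the
  movement paths of trial pairs sharing a target, after downsampling the
  position stream from 40 Hz to 4 Hz; route-based navigators produce
  similar paths to the same target and hence low dissimilarity;
* heading difference — circular difference between the average head
  orientation at object placement in the feedback phase vs the test phase
  (perceptual-matching tendency); azimuth is treated circularly, elevation
  on the linear scale.

DTW is computed by dynamic programming with a symmetric step pattern and
no window; ``symmetric2`` (diagonal steps weighted twice) is the default,
``symmetric1`` and per-step normalisation are available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import circmean, spearmanr

from .geometry import Environment

__all__ = [
    "state_occupancy",
    "path_length",
    "downsample",
    "dtw_distance",
    "path_dissimilarity",
    "circular_difference_deg",
    "heading_difference",
    "navmetric_dispersion_correlation",
]

POSITION_COLS = ["x", "y", "z"]


def _positions(traj: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(traj, pd.DataFrame):
        return traj[POSITION_COLS].to_numpy(dtype=float)
    return np.asarray(traj, dtype=float)


def state_occupancy(trajectories, env: Environment, bins_per_axis: int = 50) -> int:
    """Distinct visited bins of a regular grid, pooled over trajectories.

    Samples marginally outside the environment are clamped to the nearest
    bin.  ``trajectories`` is an iterable of sample tables (or one table).
    """
    if isinstance(trajectories, (pd.DataFrame, np.ndarray)):
        trajectories = [trajectories]
    lengths = np.asarray(env.lengths, dtype=float)
    visited = set()
    for traj in trajectories:
        pos = _positions(traj)
        if len(pos) == 0:
            continue
        frac = np.clip(pos / lengths, 0.0, np.nextafter(1.0, 0.0))
        bins = np.floor(frac * bins_per_axis).astype(int)
        visited.update(map(tuple, bins))
    return len(visited)


def path_length(traj) -> float:
    """Cumulative frame-wise 3D Euclidean distance (metres)."""
    pos = _positions(traj)
    if len(pos) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def downsample(traj: pd.DataFrame, native_rate: float = 40.0,
               target_rate: float = 4.0) -> pd.DataFrame:
    """Decimate a trajectory: keep every k-th sample starting at the first.

    k = round(native_rate / target_rate); at the target rate already
    (k = 1) this is the identity, making the operation idempotent.
    """
    if target_rate <= 0 or native_rate <= 0:
        raise ValueError("rates must be positive")
    k = max(1, int(round(native_rate / target_rate)))
    return traj.iloc[::k].reset_index(drop=True)


def dtw_distance(a, b, step_pattern: str = "symmetric2",
                 normalize: bool = False) -> float:
    """Dynamic-time-warping distance between two 3D position sequences.

    Euclidean local cost, no window.  ``symmetric2`` weights diagonal
    steps twice (normalisable by n + m); ``symmetric1`` weights all steps
    once.  Identical sequences give 0; the measure is symmetric.
    """
    A = _positions(a)
    B = _positions(b)
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each trajectory needs at least 2 samples")
    cost = cdist(A, B)
    n, m = cost.shape
    diag_w = 2.0 if step_pattern == "symmetric2" else 1.0
    if step_pattern not in ("symmetric1", "symmetric2"):
        raise ValueError(f"unknown step pattern {step_pattern!r}")
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        Dm1 = D[i - 1]
        row = D[i]
        ci = cost[i]
        for j in range(1, m):
            row[j] = min(Dm1[j - 1] + diag_w * ci[j],
                         Dm1[j] + ci[j],
                         row[j - 1] + ci[j])
    d = float(D[-1, -1])
    if normalize:
        if step_pattern != "symmetric2":
            raise ValueError("per-step normalisation requires symmetric2")
        d /= (n + m)
    return d


def path_dissimilarity(trajectories: dict, trial_targets: pd.Series | dict,
                       native_rate: float = 40.0, target_rate: float = 4.0,
                       step_pattern: str = "symmetric2",
                       normalize: bool = False) -> dict:
    """Average pairwise DTW distance between same-target trial paths.

    Parameters
    ----------
    trajectories : dict trial_id -> sample table (40 Hz).
    trial_targets : mapping trial_id -> target label.

    Returns per-target averages and their overall mean.  Trajectories are
    downsampled to ``target_rate`` before alignment.
    """
    trial_targets = dict(trial_targets)
    down = {tid: downsample(traj, native_rate, target_rate)
            for tid, traj in trajectories.items()}
    per_target = {}
    for target in sorted({str(v) for v in trial_targets.values()}):
        tids = [t for t in down if str(trial_targets[t]) == target]
        dists = [dtw_distance(down[t1], down[t2], step_pattern, normalize)
                 for i, t1 in enumerate(tids) for t2 in tids[i + 1:]]
        if dists:
            per_target[target] = float(np.mean(dists))
    overall = float(np.mean(list(per_target.values()))) if per_target else np.nan
    return {"per_target": per_target, "mean": overall}


def circular_difference_deg(a: float, b: float) -> float:
    """Absolute angular difference of two azimuths, wrapped to [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def heading_difference(feedback: pd.DataFrame, test: pd.DataFrame) -> dict:
    """Head-orientation difference at placement, feedback vs test phase.

    Inputs are per-trial placement orientations with columns
    ``target, azimuth, elevation`` (degrees).  Per target, the circular
    mean azimuth and the linear mean elevation are computed in each phase;
    their absolute differences are averaged over targets and over the two
    orientation components to one value (degrees).
    """
    rows = []
    targets = sorted(set(feedback["target"]).intersection(test["target"]))
    for target in targets:
        f = feedback[feedback["target"] == target]
        t = test[test["target"] == target]
        az_f = float(circmean(f["azimuth"], high=360.0, low=0.0))
        az_t = float(circmean(t["azimuth"], high=360.0, low=0.0))
        d_az = circular_difference_deg(az_f, az_t)
        d_el = abs(float(f["elevation"].mean()) - float(t["elevation"].mean()))
        rows.append({"target": target, "d_azimuth": d_az, "d_elevation": d_el})
    per_target = pd.DataFrame(rows)
    if not len(per_target):
        return {"per_target": per_target, "mean": np.nan}
    mean = float(0.5 * (per_target["d_azimuth"].mean()
                        + per_target["d_elevation"].mean()))
    return {"per_target": per_target, "mean": mean}


def navmetric_dispersion_correlation(metrics: pd.DataFrame,
                                     summaries: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho between each navigation metric and vertical MAD.

    ``metrics`` has one row per participant plus metric columns;
    ``summaries`` is the dispersion table (baseline rows are used).
    """
    base = summaries[summaries["environment"] == "baseline"]
    mad_v = base.groupby("participant")["MAD_vertical"].mean()
    merged = metrics.set_index("participant").join(mad_v, how="inner")
    rows = []
    for col in metrics.columns:
        if col == "participant":
            continue
        sub = merged[[col, "MAD_vertical"]].dropna()
        if len(sub) > 2:
            res = spearmanr(sub[col], sub["MAD_vertical"])
            rows.append({"metric": col, "rho": float(res.statistic),
                         "p": float(res.pvalue), "n": len(sub)})
        else:
            rows.append({"metric": col, "rho": np.nan, "p": np.nan, "n": len(sub)})
    return pd.DataFrame(rows)
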
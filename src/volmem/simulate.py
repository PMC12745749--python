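"""Synthetic participants for the 3D object-location memory task.

Generates everything the analysis modules consume, with the statistical
structure the behavioural task design prescribes:

* six free-floating targets in the baseline cube, each >= 0.26 m from every
  wall and from each other, one target's height near 1.65 m (head height);
* the full phase structure per participant — 6 familiarization, 6 initial-
  learning, 48 feedback (8 per target) and 90 test trials (5 blocks x 3
  environments x 6 trials), targets permuted within 6-trial sets, no target
  repeated on consecutive trials, start points >= 1 m from the target;
* replacement responses drawn from a ground-truth geometric model's
  probability field with axis-specific temperatures.  The default cohort
  profiles encode the locomotion-group effects: flying participants follow
  a boundary-proximity model with an inflated vertical temperature (lower
  vertical precision), walking participants a ground-proximity model with
  a deflated vertical temperature (body-as-ruler height precision);
* 40 Hz trajectories from start to response.  Walking-mode paths reuse a
  per-target waypoint template and keep intermediate samples in a head-
  height band (route-based, mutually similar paths); flying-mode paths
  roam freely through the volume.

All operations are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Environment, make_environment, make_grid
from .models import ModelSpec, prediction_field

__all__ = [
    "GenerativeProfile",
    "DEFAULT_PROFILES",
    "generate_targets",
    "generate_design",
    "simulate_responses",
    "simulate_trajectories",
    "simulate_cohort",
    "feedback_category",
    "FEEDBACK_CATEGORIES",
]

TARGET_LABELS = ("A", "B", "C", "D", "E", "F")

#: Minimum distance of targets to walls and to each other (metres).
TARGET_MARGIN = 0.26

#: Height of the head-height-anchored target (metres).
HEAD_TARGET_HEIGHT = 1.65

PHASE_TRIALS = {"familiarization": 6, "learning": 6, "feedback": 48, "test": 90}


@dataclass(frozen=True)
class GenerativeProfile:
    """Ground-truth response model of one experimental group."""

    name: str
    locomotion: str              # "walking" | "flying"
    deform_type: str             # "stretch" | "compress"
    model: str                   # generative encoding model id
    temperatures: tuple[float, float, float]
    head_height: float = 1.74    # metres, for body-referenced analyses

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be positive")

    @property
    def environments(self) -> tuple[str, str, str]:
        """Baseline plus the two deformed environments this group visits."""
        if self.deform_type == "stretch":
            return ("baseline", "HS", "VS")
        return ("baseline", "HC", "VC")


# Flying groups respond from a boundary-proximity field with a larger
# vertical temperature (vertical > horizontal dispersion); walking groups
# from a ground-proximity field with a smaller vertical temperature
# (the upright body acts as a vertical ruler).  The horizontal temperature
# is set so baseline replacement error is a few tenths of a metre.
DEFAULT_PROFILES = {
    "flying_stretch": GenerativeProfile(
        "flying_stretch", "flying", "stretch", "boundary_proximity",
        (0.020, 0.020, 0.045)),
    "flying_compress": GenerativeProfile(
        "flying_compress", "flying", "compress", "boundary_proximity",
        (0.020, 0.020, 0.045)),
    "walking_stretch": GenerativeProfile(
        "walking_stretch", "walking", "stretch", "ground_proximity",
        (0.020, 0.020, 0.003)),
    "walking_compress": GenerativeProfile(
        "walking_compress", "walking", "compress", "ground_proximity",
        (0.020, 0.020, 0.003)),
}


def generate_targets(env: Environment | None = None, seed=None,
                     margin: float = TARGET_MARGIN,
                     head_target: str | None = "D",
                     head_height: float = HEAD_TARGET_HEIGHT,
                     max_rejections: int = 100_000) -> dict[str, np.ndarray]:
    """Rejection-sample six labelled targets satisfying all margins.

    Targets are uniform in the margin-shrunk volume with pairwise
    distances >= ``margin``; the ``head_target`` (if any) has its height
    pinned to ``head_height``.  Raises ``RuntimeError`` when the margins
    are infeasible (no valid configuration after ``max_rejections`` draws).
    """
    env = env or make_environment("baseline")
    rng = np.random.default_rng(seed)
    lo = np.full(3, margin)
    hi = np.asarray(env.lengths, dtype=float) - margin
    if np.any(hi < lo):
        raise RuntimeError(f"margin {margin} m infeasible in environment "
                           f"{env.label} {env.lengths}")
    targets: dict[str, np.ndarray] = {}
    rejections = 0
    for label in TARGET_LABELS:
        while True:
            p = rng.uniform(lo, hi)
            if label == head_target:
                if not (lo[2] <= head_height <= hi[2]):
                    raise RuntimeError("head-height target outside margins")
                p[2] = head_height
            if all(np.linalg.norm(p - q) >= margin for q in targets.values()):
                targets[label] = p
                break
            rejections += 1
            if rejections > max_rejections:
                raise RuntimeError(f"target sampling failed after "
                                   f"{max_rejections} rejections")
    return targets


def _permuted_sets(rng, labels, n_sets: int, previous_last=None) -> list:
    """Concatenated permutations of ``labels`` with no consecutive repeat."""
    order = []
    last = previous_last
    for _ in range(n_sets):
        while True:
            perm = list(rng.permutation(labels))
            if perm[0] != last:
                break
        order.extend(perm)
        last = perm[-1]
    return order


def _sample_start(rng, env: Environment, target, min_distance: float = 1.0,
                  max_rejections: int = 10_000) -> np.ndarray:
    lengths = np.asarray(env.lengths, dtype=float)
    for _ in range(max_rejections):
        p = rng.uniform(0.0, 1.0, size=3) * lengths
        if np.linalg.norm(p - np.asarray(target)) >= min_distance:
            return p
    raise RuntimeError("start-point sampling failed")


def generate_design(profile: GenerativeProfile, targets: dict, seed=None,
                    participant: str = "p001") -> pd.DataFrame:
    """One participant's full trial table (no responses yet).

    Phases: 6 familiarization + 6 learning + 48 feedback trials in the
    baseline environment, then 90 test trials in 5 blocks of 3 environment
    visits (order randomised within block) x 6 trials.  Within every
    6-trial set each target appears once; no two consecutive trials share
    a target; every start point is >= 1 m from its target.
    """
    rng = np.random.default_rng(seed)
    labels = list(targets.keys())
    envs = {label: make_environment(label) for label in profile.environments}
    rows = []
    last_target = None

    def add_trials(phase, block, env_label, target_order):
        nonlocal last_target
        env = envs[env_label]
        for target in target_order:
            start = _sample_start(rng, env, targets[target])
            rows.append({
                "participant": participant, "group": profile.name,
                "locomotion": profile.locomotion, "deform_type": profile.deform_type,
                "phase": phase, "block": block, "environment": env_label,
                "target": target,
                "start_x": start[0], "start_y": start[1], "start_z": start[2],
            })
            last_target = target

    for phase, n_sets in (("familiarization", 1), ("learning", 1), ("feedback", 8)):
        order = _permuted_sets(rng, labels, n_sets, previous_last=last_target)
        add_trials(phase, 0, "baseline", order)

    for block in range(1, 6):
        env_order = list(rng.permutation(profile.environments))
        for env_label in env_order:
            order = _permuted_sets(rng, labels, 1, previous_last=last_target)
            add_trials("test", block, env_label, order)

    design = pd.DataFrame(rows)
    design.insert(5, "trial", np.arange(len(design)))
    for col in ("resp_x", "resp_y", "resp_z"):
        design[col] = np.nan
    return design


class _FieldSampler:
    """Caches normalised probability fields per (environment, target)."""

    def __init__(self, profile: GenerativeProfile, targets: dict,
                 resolution: int = 25, c: float = 1.5):
        self.profile = profile
        self.targets = {str(k): np.asarray(v, float) for k, v in targets.items()}
        self.resolution = resolution
        self.spec = ModelSpec(profile.model, c)
        self.enc_env = make_environment("baseline")
        self._cache: dict[tuple[str, str], tuple] = {}

    def field(self, env_label: str, target: str):
        key = (env_label, str(target))
        if key not in self._cache:
            grid = make_grid(make_environment(env_label), self.resolution)
            f = prediction_field(self.targets[str(target)], self.enc_env, grid,
                                 self.spec, temperatures=self.profile.temperatures,
                                 target_id=str(target))
            p = f.P.ravel()
            self._cache[key] = (grid, p / p.sum())
        return self._cache[key]

    def sample(self, rng, env_label: str, target: str, n: int = 1) -> np.ndarray:
        """Draw responses: a field bin by probability + uniform in-bin jitter."""
        grid, p = self.field(env_label, target)
        flat = rng.choice(len(p), size=n, p=p)
        idx = np.stack(np.unravel_index(flat, grid.shape), axis=1)
        sizes = np.asarray(grid.bin_sizes)
        low = idx * sizes
        return low + rng.uniform(0.0, 1.0, size=(n, 3)) * sizes


def simulate_responses(design: pd.DataFrame, profile: GenerativeProfile,
                       targets: dict, seed=None, resolution: int = 25,
                       c: float = 1.5, phases=("feedback", "test"),
                       sampler: _FieldSampler | None = None) -> pd.DataFrame:
    """Fill replacement responses drawn from the profile's model field."""
    rng = np.random.default_rng(seed)
    sampler = sampler or _FieldSampler(profile, targets, resolution, c)
    design = design.copy()
    mask = design["phase"].isin(phases)
    for row_idx in design.index[mask]:
        env_label = design.at[row_idx, "environment"]
        target = design.at[row_idx, "target"]
        resp = sampler.sample(rng, env_label, target, n=1)[0]
        design.loc[row_idx, ["resp_x", "resp_y", "resp_z"]] = resp
    return design


#: Walking-mode head-height band for intermediate trajectory samples (m).
WALK_BAND = (0.5, 1.9)


def _heading(deltas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    az = np.degrees(np.arctan2(deltas[:, 1], deltas[:, 0])) % 360.0
    horiz = np.hypot(deltas[:, 0], deltas[:, 1])
    el = np.degrees(np.arctan2(deltas[:, 2], horiz))
    return az, np.clip(el, -90.0, 90.0)


def _polyline_samples(points: list[np.ndarray], speed: float,
                      rate: float) -> np.ndarray:
    """Positions along a polyline at constant speed and sample rate."""
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = max(2, int(math.floor(total / speed * rate)) + 1)
    s = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for a in range(3):
        out[:, a] = np.interp(s, cum, pts[:, a])
    return out


def simulate_trajectories(design: pd.DataFrame, mode: str, seed=None,
                          sample_rate: float = 40.0, speed: float = 1.0,
                          phases=("feedback", "test"),
                          walk_band: tuple[float, float] = WALK_BAND) -> dict:
    """40 Hz start -> waypoints -> response paths for each trial.

    Walking mode routes through one fixed waypoint template per target
    (plus small per-trial jitter) with intermediate z clamped to the
    head-height band; flying mode inserts two fresh uniform waypoints per
    trial.  Returns ``{trial_id: DataFrame(t, x, y, z, azimuth, elevation)}``.
    """
    if mode not in ("walking", "flying"):
        raise ValueError("mode must be 'walking' or 'flying'")
    rng = np.random.default_rng(seed)
    trajectories = {}
    envs = {label: make_environment(label)
            for label in design["environment"].unique()}
    templates: dict[tuple[str, str], np.ndarray] = {}
    rows = design[design["phase"].isin(phases)].dropna(subset=["resp_x"])
    for _, row in rows.iterrows():
        env = envs[row["environment"]]
        lengths = np.asarray(env.lengths)
        start = np.array([row["start_x"], row["start_y"], row["start_z"]])
        resp = np.array([row["resp_x"], row["resp_y"], row["resp_z"]])
        if mode == "walking":
            key = (row["environment"], row["target"])
            if key not in templates:
                wp = rng.uniform(0.15, 0.85, size=3) * lengths
                wp[2] = rng.uniform(*walk_band)
                templates[key] = wp
            wp = templates[key] + rng.normal(0.0, 0.05, size=3)
            wp = np.clip(wp, 0.0, lengths)
            wp[2] = np.clip(wp[2], *walk_band)
            p1 = np.array([start[0], start[1], np.clip(start[2], *walk_band)])
            p2 = np.array([resp[0], resp[1], np.clip(resp[2], *walk_band)])
            points = [start, p1, wp, p2, resp]
        else:
            w = rng.uniform(0.05, 0.95, size=(2, 3)) * lengths
            points = [start, w[0], w[1], resp]
        pos = _polyline_samples(points, speed, sample_rate)
        deltas = np.diff(pos, axis=0)
        deltas = np.vstack([deltas, deltas[-1]])  # hold last heading
        az, el = _heading(deltas)
        t = np.arange(len(pos)) / sample_rate
        trial_id = f"{row['participant']}_{int(row['trial']):03d}"
        trajectories[trial_id] = pd.DataFrame(
            {"trial_id": trial_id, "t": t, "x": pos[:, 0], "y": pos[:, 1],
             "z": pos[:, 2], "azimuth": az, "elevation": el})
    return trajectories


def simulate_cohort(n_per_group: int = 20, seed: int = 0,
                    profiles: dict | None = None, targets: dict | None = None,
                    resolution: int = 25, c: float = 1.5,
                    with_trajectories: bool = False):
    """A full synthetic cohort: targets, trials (and optional trajectories).

    Returns ``(trials, targets)`` or ``(trials, targets, trajectories)``.
    Participants are labelled p001, p002, ... across groups; every group
    uses the same fixed target set.
    """
    profiles = profiles or DEFAULT_PROFILES
    root = np.random.SeedSequence(seed)
    target_seed, *participant_seeds = root.spawn(1 + n_per_group * len(profiles))
    targets = targets or generate_targets(seed=target_seed)
    frames = []
    trajectories = {}
    pid_counter = 0
    samplers = {name: _FieldSampler(p, targets, resolution, c)
                for name, p in profiles.items()}
    for name, profile in profiles.items():
        for _ in range(n_per_group):
            ss = participant_seeds[pid_counter]
            pid_counter += 1
            pid = f"p{pid_counter:03d}"
            s_design, s_resp, s_traj = ss.spawn(3)
            design = generate_design(profile, targets, seed=s_design,
                                     participant=pid)
            design = simulate_responses(design, profile, targets, seed=s_resp,
                                        resolution=resolution, c=c,
                                        sampler=samplers[name])
            frames.append(design)
            if with_trajectories:
                trajectories.update(simulate_trajectories(
                    design, profile.locomotion, seed=s_traj))
    trials = pd.concat(frames, ignore_index=True)
    if with_trajectories:
        return trials, targets, trajectories
    return trials, targets


FEEDBACK_CATEGORIES = ("very good", "good", "intermediate", "bad", "very bad")


def feedback_category(error: float, base_plane: float = 3.0) -> tuple[str, tuple]:
    """Accuracy feedback category from the replacement error.

    Thresholds are d_max / k^2 for k = 5, 4, 3, 2 with d_max the diagonal
    of the base_plane x base_plane floor (sqrt(18) m for the 3 m room):
    0.17 / 0.27 / 0.47 / 1.06 m at two decimals.
    """
    if error < 0:
        raise ValueError("error must be non-negative")
    d_max = math.hypot(base_plane, base_plane)
    thresholds = tuple(d_max / k ** 2 for k in (5, 4, 3, 2))
    for threshold, category in zip(thresholds, FEEDBACK_CATEGORIES):
        if error < threshold:
            return category, thresholds
    return FEEDBACK_CATEGORIES[-1], thresholds
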
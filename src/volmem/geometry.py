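"""Cuboid environments, deformations, and spatial grids.

The task space is a room-sized cuboid enclosure. Training takes place in a
cubic baseline environment (3 x 3 x 3 m); memory is probed both there and in
four deformed variants in which exactly one axis is stretched (x 1.33) or
compressed (x 0.67):

    ``HS`` / ``HC``  horizontal stretch / compression (x axis)
    ``VS`` / ``VC``  vertical stretch / compression (z axis)

Coordinates are environment-local: origin at a fixed floor corner, axes
aligned with the walls, z vertical (z = 0 on the ground).  All environments
share the origin corner, so the ground and two side walls are invariant
under deformation.  Wall naming convention used throughout the package:

    ground  z = 0      ceiling z = L_z
    north   y = 0      south   y = L_y
    east    x = 0      west    x = L_x

Prediction fields and occupancy maps live on regular grids of half-open
bins.  The baseline resolution is 25 bins per axis; a deformed axis keeps
the baseline bin size, i.e. it gets ``round(25 * factor)`` bins (33 for a
stretched, 17 for a compressed axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ENVIRONMENT_LABELS",
    "DEFORMED_AXIS",
    "DEFORMATION_AXIS_NAME",
    "Environment",
    "Grid",
    "make_environment",
    "make_grid",
    "point_to_bin",
    "bin_center",
    "wall_distances",
]

#: Valid environment labels.
ENVIRONMENT_LABELS = ("baseline", "HS", "HC", "VS", "VC")

#: Index of the deformed coordinate axis (0 = x, 2 = z) per deformed label.
DEFORMED_AXIS = {"HS": 0, "HC": 0, "VS": 2, "VC": 2}

#: Deformation plane ("horizontal"/"vertical") per deformed label.
DEFORMATION_AXIS_NAME = {"HS": "horizontal", "HC": "horizontal",
                         "VS": "vertical", "VC": "vertical"}

_CLAMP_TOL = 1e-9  # metres; responses marginally outside the walls clamp


@dataclass(frozen=True)
class Environment:
    """A cuboid enclosure with axis lengths in metres."""

    label: str
    lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.lengths) != 3:
            raise ValueError("lengths must be a 3-tuple")
        if any(length < 0 for length in self.lengths):
            raise ValueError(f"axis lengths must be non-negative: {self.lengths}")

    @property
    def L_x(self) -> float:
        return self.lengths[0]

    @property
    def L_y(self) -> float:
        return self.lengths[1]

    @property
    def L_z(self) -> float:
        return self.lengths[2]

    @property
    def volume(self) -> float:
        return self.lengths[0] * self.lengths[1] * self.lengths[2]

    def contains(self, point, tol: float = _CLAMP_TOL) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= -tol) and np.all(p <= np.asarray(self.lengths) + tol))


def make_environment(label: str, base_length: float = 3.0,
                     stretch: float = 1.33, compress: float = 0.67) -> Environment:
    """Build the baseline cube or one of the four deformed cuboids.

    Parameters
    ----------
    label : {"baseline", "HS", "HC", "VS", "VC"}
        ``baseline`` is a cube of side ``base_length``; the others deform
        exactly one axis by ``stretch`` or ``compress``.
    """
    if label not in ENVIRONMENT_LABELS:
        raise ValueError(f"unknown environment label {label!r}; "
                         f"expected one of {ENVIRONMENT_LABELS}")
    lengths = [base_length] * 3
    if label != "baseline":
        factor = stretch if label.endswith("S") else compress
        lengths[DEFORMED_AXIS[label]] = base_length * factor
    return Environment(label, tuple(lengths))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Grid:
    """Regular binning of an environment into half-open bins.

    ``shape`` gives bins per axis; ``edges`` the (n+1)-length edge arrays.
    Bins tile ``[0, L_axis)`` exactly.
    """

    environment: Environment
    shape: tuple[int, int, int]
    edges: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be positive: {self.shape}")
        if self.edges is None:
            edges = tuple(np.linspace(0.0, L, n + 1)
                          for L, n in zip(self.environment.lengths, self.shape))
            object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.shape))

    @property
    def bin_sizes(self) -> tuple[float, float, float]:
        return tuple(L / n for L, n in zip(self.environment.lengths, self.shape))

    def axis_centers(self, axis: int) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis bin-center coordinate arrays."""
        return tuple(self.axis_centers(a) for a in range(3))


def make_grid(env: Environment, base_resolution: int = 25) -> Grid:
    """Grid an environment at a baseline per-axis resolution.

    Undeformed axes get ``base_resolution`` bins; a deformed axis gets
    ``round(base_resolution * factor)`` bins (round half up), which keeps
    the bin size within half a bin of the baseline bin size.
    """
    if base_resolution < 2:
        raise ValueError("base_resolution must be >= 2")
    if env.label in DEFORMED_AXIS:  # undeformed axes carry the base length
        base = next(env.lengths[a] for a in range(3)
                    if a != DEFORMED_AXIS[env.label])
    else:
        base = env.lengths[0]
    shape = []
    for axis, L in enumerate(env.lengths):
        factor = L / base
        shape.append(_round_half_up(base_resolution * factor))
    return Grid(env, tuple(shape))


def point_to_bin(point, grid: Grid, tol: float = _CLAMP_TOL) -> tuple[int, int, int]:
    """Index triple of the half-open bin containing ``point``.

    Points on the upper boundary, or within ``tol`` metres outside the
    environment, are clamped to the nearest valid bin; anything farther out
    raises ``ValueError``.
    """
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError(f"non-finite point {point}")
    idx = []
    for axis in range(3):
        L = grid.environment.lengths[axis]
        n = grid.shape[axis]
        c = p[axis]
        if c < -tol or c > L + tol:
            raise ValueError(f"point {tuple(p)} outside environment "
                             f"{grid.environment.label} on axis {axis}")
        i = int(math.floor(c / L * n)) if L > 0 else 0
        idx.append(min(max(i, 0), n - 1))
    return tuple(idx)


def bin_center(index: tuple[int, int, int], grid: Grid) -> np.ndarray:
    """Centre coordinates (metres) of the bin at ``index``."""
    return np.array([grid.axis_centers(a)[index[a]] for a in range(3)])


def wall_distances(point, env: Environment, tol: float = _CLAMP_TOL) -> dict[str, float]:
    """Perpendicular distances to the six walls.

    Returns a dict keyed ``ceiling, ground, north, south, east, west``;
    each opposing pair sums to the corresponding axis length.
    """
    p = np.asarray(point, dtype=float)
    if not env.contains(p, tol=tol):
        raise ValueError(f"point {tuple(p)} outside environment {env.label}")
    x, y, z = (float(np.clip(p[a], 0.0, env.lengths[a])) for a in range(3))
    return {
        "ceiling": env.L_z - z,
        "ground": z,
        "north": y,
        "south": env.L_y - y,
        "east": x,
        "west": env.L_x - x,
    }
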
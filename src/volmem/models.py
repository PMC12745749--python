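"""Geometric encoding models and their gridded prediction fields.

Four models formalise how a remembered 3D object location may be encoded
relative to the walls of a cuboid enclosure, and therefore where it should
be replaced once the enclosure is deformed:

``fixed_distance``
    the perpendicular distance to the *nearest* wall on each axis,
    a 3-vector (d_CG, d_NS, d_EW);
``fixed_ratio``
    the proportion of each axis traversed, i.e. the distance to a
    designated wall divided by the axis length, a 3-vector
    (r_CG, r_NS, r_EW) with the ground, north and east walls as
    numerators;
``boundary_proximity``
    the nonlinear proximity 1/(d + c) to all six walls (C, G, N, S, E, W),
    a 6-vector.  With the proximity constant c fixed at half the baseline
    axis length (1.5 m) this interpolates between fixed-distance behaviour
    near walls and fixed-ratio behaviour at the centre, mimicking place
    predictions derived from boundary-vector-cell population activity;
``ground_proximity``
    boundary proximity without the ceiling term (G, N, S, E, W), a proxy
    for ground-anchored, body-based height cues available when walking.

A prediction field for a target is built in three layers on the test
environment's grid: the dissimilarity D (L2 norm between the target's
feature vector in the encoding environment and each test bin centre's
feature vector), the similarity S = max(D) - D, and the probability P
obtained by a product of per-axis softmaxes with axis-specific temperature
parameters T:

    P_xyz = prod_a  exp(S_xyz / T_a) / sum_{a'} exp(S / T_a)

where each denominator sums along the corresponding axis.  Low temperatures
give peaked predictions, high temperatures approach uniformity.  P is not
globally renormalised by default (the per-axis product is used as printed);
pass ``renormalize=True`` for a field that sums to one over the volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .geometry import Environment, Grid

__all__ = [
    "MODEL_IDS",
    "ModelSpec",
    "feature_fixed_distance",
    "feature_fixed_ratio",
    "feature_boundary_proximity",
    "feature_ground_proximity",
    "feature_vectors",
    "PredictionField",
    "dissimilarity_field",
    "similarity_field",
    "probability_field",
    "log_probability_field",
    "prediction_field",
    "field_to_frame",
]

MODEL_IDS = ("fixed_distance", "fixed_ratio", "boundary_proximity", "ground_proximity")

#: Default proximity constant: half the cubic baseline axis length (metres).
DEFAULT_C = 1.5


@dataclass(frozen=True)
class ModelSpec:
    """An encoding model identifier plus its proximity constant."""

    model: str
    c: float = DEFAULT_C

    def __post_init__(self) -> None:
        if self.model not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODEL_IDS}")
        if self.c <= 0:
            raise ValueError("proximity constant c must be > 0")


def _coords(points) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    return p[:, 0], p[:, 1], p[:, 2], single


def _check_inside(points, env: Environment) -> None:
    p = np.atleast_2d(np.asarray(points, dtype=float))
    lo = p.min(axis=0)
    hi = p.max(axis=0)
    if np.any(lo < -1e-9) or np.any(hi > np.asarray(env.lengths) + 1e-9):
        raise ValueError(f"point(s) outside environment {env.label}")


def feature_vectors(points, env: Environment, spec: ModelSpec) -> np.ndarray:
    """Model feature vectors for one point (1-D) or many points ((n, k)).

    Component order follows the wall convention of :mod:`volmem.geometry`:
    axes are reported vertical-first (CG, NS, EW) for the 3-vectors and
    (C, G, N, S, E, W) for the proximity models.
    """
    _check_inside(points, env)
    x, y, z, single = _coords(points)
    Lx, Ly, Lz = env.lengths
    d = {  # distances to the six walls
        "C": Lz - z, "G": z,
        "N": y, "S": Ly - y,
        "E": x, "W": Lx - x,
    }
    if spec.model == "fixed_distance":
        out = np.stack([np.minimum(d["C"], d["G"]),
                        np.minimum(d["N"], d["S"]),
                        np.minimum(d["E"], d["W"])], axis=-1)
    elif spec.model == "fixed_ratio":
        out = np.stack([d["G"] / Lz, d["N"] / Ly, d["E"] / Lx], axis=-1)
    elif spec.model == "boundary_proximity":
        out = np.stack([1.0 / (d[w] + spec.c) for w in "CGNSEW"], axis=-1)
    else:  # ground_proximity
        out = np.stack([1.0 / (d[w] + spec.c) for w in "GNSEW"], axis=-1)
    return out[0] if single else out


def feature_fixed_distance(point, env: Environment) -> np.ndarray:
    """Per-axis distance to the nearest wall, order (CG, NS, EW)."""
    return feature_vectors(point, env, ModelSpec("fixed_distance"))


def feature_fixed_ratio(point, env: Environment) -> np.ndarray:
    """Per-axis proportion of distance to the ground/north/east wall."""
    return feature_vectors(point, env, ModelSpec("fixed_ratio"))


def feature_boundary_proximity(point, env: Environment, c: float = DEFAULT_C) -> np.ndarray:
    """Proximity 1/(d + c) to all six walls, order (C, G, N, S, E, W)."""
    return feature_vectors(point, env, ModelSpec("boundary_proximity", c))


def feature_ground_proximity(point, env: Environment, c: float = DEFAULT_C) -> np.ndarray:
    """Proximity to the five non-ceiling walls, order (G, N, S, E, W)."""
    return feature_vectors(point, env, ModelSpec("ground_proximity", c))


@dataclass
class PredictionField:
    """Gridded D / S / P layers for one target under one model."""

    grid: Grid
    target_id: str
    spec: ModelSpec
    D: np.ndarray
    S: np.ndarray | None = None
    P: np.ndarray | None = None
    log_P: np.ndarray | None = None
    temperatures: tuple[float, float, float] | None = None


def dissimilarity_field(target, enc_env: Environment, test_grid: Grid,
                        spec: ModelSpec, target_id: str = "") -> PredictionField:
    """Dissimilarity layer: L2 feature distance, target vs every test bin.

    The target's feature vector is evaluated at its exact continuous
    coordinates in the encoding environment; test features at bin centres
    of the (possibly deformed) test environment.
    """
    _check_inside(target, enc_env)
    v_target = feature_vectors(np.asarray(target, float), enc_env, spec)
    cx, cy, cz = test_grid.centers()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    V = feature_vectors(pts, test_grid.environment, spec)
    D = np.linalg.norm(V - v_target, axis=1).reshape(test_grid.shape)
    return PredictionField(test_grid, target_id, spec, D=D)


def similarity_field(field: PredictionField) -> PredictionField:
    """Similarity layer S = max(D) - D; the max is over the whole field."""
    if field.D is None or field.D.size == 0:
        raise ValueError("dissimilarity layer missing or empty")
    field.S = field.D.max() - field.D
    return field


def log_probability_field(S: np.ndarray, temperatures, renormalize: bool = False) -> np.ndarray:
    """Log of the per-axis softmax product, computed stably in log space."""
    T = np.asarray(temperatures, dtype=float)
    if T.shape != (3,) or np.any(T <= 0):
        raise ValueError(f"temperatures must be three positive values, got {temperatures}")
    log_p = np.zeros_like(S)
    for axis in range(3):
        scaled = S / T[axis]
        log_p += scaled - logsumexp(scaled, axis=axis, keepdims=True)
    if renormalize:
        log_p -= logsumexp(log_p)
    return log_p


def probability_field(field: PredictionField, temperatures,
                      renormalize: bool = False) -> PredictionField:
    """Probability layer from the similarity layer and per-axis temperatures."""
    if field.S is None:
        raise ValueError("similarity layer missing; call similarity_field first")
    field.log_P = log_probability_field(field.S, temperatures, renormalize=renormalize)
    field.P = np.exp(field.log_P)
    field.temperatures = tuple(float(t) for t in np.asarray(temperatures, float))
    return field


def prediction_field(target, enc_env: Environment, test_grid: Grid, spec: ModelSpec,
                     temperatures=None, renormalize: bool = False,
                     target_id: str = "") -> PredictionField:
    """Build D and S layers (and P, if temperatures are given) in one call."""
    field = similarity_field(dissimilarity_field(target, enc_env, test_grid,
                                                 spec, target_id=target_id))
    if temperatures is not None:
        field = probability_field(field, temperatures, renormalize=renormalize)
    return field


def field_to_frame(field: PredictionField):
    """Flatten a field to a DataFrame (bin indices + D/S/P columns)."""
    import pandas as pd

    ix, iy, iz = np.meshgrid(*[np.arange(n) for n in field.grid.shape], indexing="ij")
    data = {"ix": ix.ravel(), "iy": iy.ravel(), "iz": iz.ravel(), "D": field.D.ravel()}
    if field.S is not None:
        data["S"] = field.S.ravel()
    if field.P is not None:
        data["P"] = field.P.ravel()
    return pd.DataFrame(data)
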
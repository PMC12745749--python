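"""Replacement error, chance level, and MAD-based anisotropy analyses.

Replacement precision is summarised per participant x environment x target
by the median absolute deviation (MAD, metres, no consistency scaling) of
the responses along each axis.  Vertical precision is the z-axis MAD;
horizontal precision the mean of the x and y MADs.  The anisotropy index

    AI = ln(MAD_vertical) - ln(MAD_horizontal)

is positive when vertical dispersion exceeds horizontal.  Deforming one
axis of the familiar environment by a factor f should rescale dispersion
along that axis by f, so the deformation-induced change dAI = AI_deformed
- AI_baseline has analytic expected values ln(V/H):

    VS: ln(1.33/1) = +0.285      HC: ln(1/0.67) = +0.400
    HS: ln(1/1.33) = -0.285      VC: ln(0.67/1) = -0.400

Observed dAI are tested against these per condition and locomotion group
(one-sample t, Bonferroni-corrected for 8 comparisons).  Chance-level
error for the replacement task is estimated by simulating uniform random
responses per target.  Boundary-distance and head-distance correlations
relate per-target MADs to the target's distance from the nearest wall
(per dimension) or from the participant's head height (Spearman).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, ttest_1samp

from .geometry import Environment, make_environment

__all__ = [
    "EXPECTED_DELTA_AI",
    "expected_delta_ai",
    "euclidean_error",
    "chance_level",
    "mad",
    "summarize_dispersion",
    "participant_anisotropy",
    "delta_ai",
    "boundary_distance_correlation",
    "head_distance_correlation",
]

logger = logging.getLogger(__name__)

RESPONSE_COLS = ["resp_x", "resp_y", "resp_z"]


def expected_delta_ai(stretch: float = 1.33, compress: float = 0.67) -> dict[str, float]:
    """Analytic dAI = ln(V/H) induced by a single-axis deformation."""
    return {
        "VS": math.log(stretch),
        "HC": math.log(1.0 / compress),
        "HS": math.log(1.0 / stretch),
        "VC": math.log(compress),
    }


#: Expected dAI per condition at the standard 1.33 / 0.67 factors.
EXPECTED_DELTA_AI = expected_delta_ai()


def euclidean_error(response, target) -> float:
    """3D Euclidean distance (metres) between a response and its target."""
    r = np.asarray(response, dtype=float)
    t = np.asarray(target, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(r - t))


def chance_level(targets, env: Environment, n: int = 10_000, seed=None,
                 n_boot: int = 2000, ci: float = 0.95) -> dict:
    """Chance-level replacement error from uniform random responses.

    Simulates ``n`` uniform points in the environment volume per target and
    measures their Euclidean error.  Returns per-target means, the pooled
    mean over all targets x simulations, the mean of per-target means, and
    a percentile bootstrap CI of the pooled mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    targets = {str(k): np.asarray(v, float) for k, v in dict(targets).items()}
    lengths = np.asarray(env.lengths, dtype=float)
    per_target = {}
    all_errors = []
    for label, t in targets.items():
        pts = rng.uniform(0.0, 1.0, size=(n, 3)) * lengths
        err = np.linalg.norm(pts - t, axis=1)
        per_target[label] = float(err.mean())
        all_errors.append(err)
    pooled = np.concatenate(all_errors)
    boot_means = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(pooled), size=len(pooled))
        boot_means[b] = pooled[idx].mean()
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha])
    return {
        "per_target": per_target,
        "pooled_mean": float(pooled.mean()),
        "mean_of_target_means": float(np.mean(list(per_target.values()))),
        "ci": (float(lo), float(hi)),
        "n": n,
    }


def mad(values) -> float:
    """Median absolute deviation about the median (no scaling constant)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("mad requires at least 2 values")
    return float(np.median(np.abs(v - np.median(v))))


def summarize_dispersion(trials: pd.DataFrame, min_trials: int = 2) -> pd.DataFrame:
    """Per-axis MADs and anisotropy index per participant x environment x target.

    Groups with fewer than ``min_trials`` responses are dropped.  AI is NaN
    whenever either MAD is zero (log undefined).
    """
    trials = trials.dropna(subset=RESPONSE_COLS)
    rows = []
    for (pid, env, target), sub in trials.groupby(
            ["participant", "environment", "target"], sort=True):
        if len(sub) < min_trials:
            continue
        mads = [mad(sub[c]) for c in RESPONSE_COLS]
        mad_h = 0.5 * (mads[0] + mads[1])
        mad_v = mads[2]
        ai = math.log(mad_v) - math.log(mad_h) if mad_v > 0 and mad_h > 0 else np.nan
        rows.append({"participant": pid, "environment": env, "target": target,
                     "MAD_x": mads[0], "MAD_y": mads[1], "MAD_z": mads[2],
                     "MAD_horizontal": mad_h, "MAD_vertical": mad_v,
                     "AI": ai, "n_trials": len(sub)})
    return pd.DataFrame(rows)


def participant_anisotropy(trials: pd.DataFrame) -> pd.DataFrame:
    """Participant x environment AI from pooled median-centred responses.

    Responses are median-centred per target and axis, pooled across
    targets within participant and environment, and the per-axis MAD of
    the pooled deviations taken; this uses all of a participant's trials
    for one MAD instead of a handful per target.
    """
    trials = trials.dropna(subset=RESPONSE_COLS)
    rows = []
    for (pid, env), sub in trials.groupby(["participant", "environment"],
                                          sort=True):
        centered = sub[RESPONSE_COLS] - sub.groupby("target")[
            RESPONSE_COLS].transform("median")
        mads = [mad(centered[c]) for c in RESPONSE_COLS]
        mad_h = 0.5 * (mads[0] + mads[1])
        mad_v = mads[2]
        rows.append({"participant": pid, "environment": env,
                     "MAD_horizontal": mad_h, "MAD_vertical": mad_v,
                     "AI": (math.log(mad_v) - math.log(mad_h)
                            if mad_v > 0 and mad_h > 0 else np.nan),
                     "n_trials": len(sub)})
    return pd.DataFrame(rows)


def _participant_ai(summaries: pd.DataFrame) -> pd.DataFrame:
    """Participant x environment AI from per-target dispersion summaries.

    MADs are averaged over targets within participant and environment
    before the log-ratio, so a single noisy target cannot dominate AI.
    """
    agg = (summaries.groupby(["participant", "environment"])
           [["MAD_horizontal", "MAD_vertical"]].mean().reset_index())
    agg["AI"] = np.log(agg["MAD_vertical"]) - np.log(agg["MAD_horizontal"])
    return agg


def delta_ai(summaries: pd.DataFrame, groups: pd.Series | None = None,
             stretch: float = 1.33, compress: float = 0.67,
             n_comparisons: int = 8) -> dict[str, pd.DataFrame]:
    """Observed vs expected deformation-induced AI change.

    ``summaries`` is either a dispersion-summary table (per-target MADs,
    averaged within participant x environment) or a raw trial table with
    response columns, in which case AI comes from pooled median-centred
    responses via :func:`participant_anisotropy` (more stable).

    Returns ``{"per_participant": ..., "tests": ...}``.  Per participant and
    deformed environment, dAI = AI_deformed - AI_baseline; expected values
    come from :func:`expected_delta_ai`.  One-sample t-tests against the
    expected value are run per condition (and per locomotion group when
    ``groups`` maps participant -> group), Bonferroni-corrected.
    """
    expected = expected_delta_ai(stretch, compress)
    if "resp_x" in summaries.columns:  # raw trials: pool centred responses
        ai = participant_anisotropy(summaries)
    else:
        ai = _participant_ai(summaries)
    wide = ai.pivot(index="participant", columns="environment", values="AI")
    if "baseline" not in wide.columns:
        raise ValueError("summaries contain no baseline environment")
    rows = []
    for env in wide.columns:
        if env == "baseline":
            continue
        d = wide[env] - wide["baseline"]
        for pid, val in d.dropna().items():
            rows.append({"participant": pid, "condition": env,
                         "delta_ai": float(val),
                         "expected_delta_ai": expected.get(env, 0.0)})
    per = pd.DataFrame(rows)
    if groups is not None and len(per):
        per["group"] = per["participant"].map(groups)

    test_rows = []
    by = ["condition", "group"] if "group" in per.columns else ["condition"]
    if len(per):
        for key, sub in per.groupby(by, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            exp = sub["expected_delta_ai"].iloc[0]
            if len(sub) > 1 and sub["delta_ai"].std(ddof=1) > 0:
                t, p = ttest_1samp(sub["delta_ai"], popmean=exp)
                p_adj = min(1.0, p * n_comparisons)
            else:
                t, p, p_adj = np.nan, np.nan, np.nan
            row = dict(zip(by, key))
            row.update({"expected_delta_ai": exp,
                        "mean_delta_ai": float(sub["delta_ai"].mean()),
                        "t": t, "p": p, "p_bonferroni": p_adj, "n": len(sub)})
            test_rows.append(row)
    return {"per_participant": per, "tests": pd.DataFrame(test_rows)}


def _nearest_wall_distances(target, env: Environment) -> tuple[float, float]:
    """(horizontal, vertical) distance of a point to its nearest wall."""
    t = np.asarray(target, dtype=float)
    Lx, Ly, Lz = env.lengths
    horiz = min(t[0], Lx - t[0], t[1], Ly - t[1])
    vert = min(t[2], Lz - t[2])
    return float(horiz), float(vert)


def _spearman(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        logger.warning("all-tied input to Spearman correlation; reporting NaN")
        return np.nan
    return float(spearmanr(x, y).statistic)


def _group_ttest(rhos: pd.Series) -> dict:
    rhos = rhos.dropna()
    if len(rhos) > 1 and rhos.std(ddof=1) > 0:
        t, p = ttest_1samp(rhos, popmean=0.0)
    else:
        t, p = np.nan, np.nan
    return {"mean_rho": float(rhos.mean()) if len(rhos) else np.nan,
            "t": t, "p": p, "n": int(len(rhos))}


def boundary_distance_correlation(summaries: pd.DataFrame, targets,
                                  env: Environment | None = None) -> dict:
    """Spearman rho between per-target MAD and target-to-boundary distance.

    Computed per participant, separately for the horizontal dimension
    (nearest side wall vs horizontal MAD) and the vertical dimension
    (nearest of ground/ceiling vs vertical MAD), then tested against zero
    across participants.  Requires >= 4 targets per participant.
    """
    env = env or make_environment("baseline")
    targets = {str(k): np.asarray(v, float) for k, v in dict(targets).items()}
    dist = {k: _nearest_wall_distances(v, env) for k, v in targets.items()}
    rows = []
    base = summaries[summaries["environment"] == "baseline"]
    for pid, sub in base.groupby("participant", sort=True):
        if sub["target"].nunique() < 4:
            continue
        d_h = [dist[str(t)][0] for t in sub["target"]]
        d_v = [dist[str(t)][1] for t in sub["target"]]
        rows.append({"participant": pid,
                     "rho_horizontal": _spearman(d_h, sub["MAD_horizontal"]),
                     "rho_vertical": _spearman(d_v, sub["MAD_vertical"])})
    per = pd.DataFrame(rows)
    tests = {dim: _group_ttest(per[f"rho_{dim}"]) if len(per) else {}
             for dim in ("horizontal", "vertical")}
    return {"per_participant": per, "tests": tests}


def head_distance_correlation(summaries: pd.DataFrame, targets,
                              participant_height: float | pd.Series = 1.74) -> dict:
    """Spearman rho between vertical MAD and |target height - head height|."""
    targets = {str(k): np.asarray(v, float) for k, v in dict(targets).items()}
    rows = []
    base = summaries[summaries["environment"] == "baseline"]
    for pid, sub in base.groupby("participant", sort=True):
        h = (participant_height.get(pid, np.nan)
             if isinstance(participant_height, (pd.Series, dict))
             else participant_height)
        d = [abs(targets[str(t)][2] - h) for t in sub["target"]]
        rows.append({"participant": pid,
                     "rho": _spearman(d, sub["MAD_vertical"])})
    per = pd.DataFrame(rows)
    return {"per_participant": per,
            "tests": _group_ttest(per["rho"]) if len(per) else {}}
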
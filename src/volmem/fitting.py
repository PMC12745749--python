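"""Temperature fitting, likelihood evaluation and model comparison.

The central object is :class:`PlacementModel`, a scikit-learn-style
estimator.  ``fit`` takes one participant's baseline test trials and finds
the per-axis softmax temperatures (T_x, T_y, T_z) that maximise the summed
log-likelihood of the observed replacements under the chosen geometric
encoding model, using L-BFGS-B on log-temperatures with fixed multi-starts.
``score`` / ``log_likelihood`` then evaluate the fitted model on further
trials — in particular on trials from deformed test environments, which is
where the four encoding models make diverging predictions.

Absolute fit is expressed as pseudo-R² = 1 − LL_model / LL_chance, with
chance a uniform distribution over the spatial bins of each trial's test
environment; 1 means perfect prediction, 0 chance level, negative values
worse than chance.

Cohort-level helpers (:func:`fit_cohort`, :func:`compare_models`) loop the
estimator over participants and models and run the paired comparisons.

Trial tables are pandas DataFrames with (at least) the columns
``participant, phase, environment, target, resp_x, resp_y, resp_z``;
target coordinates are supplied separately (mapping label -> (x, y, z)).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import ttest_rel

from sklearn.base import BaseEstimator

from .geometry import (DEFORMATION_AXIS_NAME, Environment, make_environment,
                       make_grid, point_to_bin)
from .models import (MODEL_IDS, ModelSpec, PredictionField,
                     log_probability_field, prediction_field)

__all__ = [
    "PlacementModel",
    "trial_log_likelihood",
    "fit_temperatures",
    "evaluate_deformed",
    "pseudo_r2",
    "fit_cohort",
    "compare_models",
]

#: Floor on a single trial's probability, preventing -inf contributions.
P_FLOOR = 1e-300
LOG_P_FLOOR = float(np.log(P_FLOOR))

RESPONSE_COLS = ["resp_x", "resp_y", "resp_z"]


def targets_to_dict(targets) -> dict[str, np.ndarray]:
    """Accept a {label: xyz} mapping or a DataFrame (target, x, y, z)."""
    if isinstance(targets, pd.DataFrame):
        return {str(r["target"]): np.array([r["x"], r["y"], r["z"]], float)
                for _, r in targets.iterrows()}
    return {str(k): np.asarray(v, dtype=float) for k, v in targets.items()}


def pseudo_r2(ll_model: float, ll_chance: float) -> float:
    """1 − LL_model / LL_chance against a uniform-over-bins chance model."""
    if ll_chance == 0:
        raise ValueError("chance log-likelihood must be negative, got 0")
    return 1.0 - ll_model / ll_chance


def trial_log_likelihood(response, field: PredictionField) -> float:
    """Log-probability of one replacement under a field's P layer (floored)."""
    if field.log_P is None:
        raise ValueError("field has no probability layer")
    idx = point_to_bin(response, field.grid)
    return float(max(field.log_P[idx], LOG_P_FLOOR))


class _LikelihoodKernel:
    """Precomputed similarity lines giving cheap LL(T) for a trial set.

    For the non-renormalised per-axis softmax product, the log-probability
    of a response bin (i, j, k) only involves the three similarity lines
    through that bin, so the optimiser's objective never rebuilds fields.
    """

    def __init__(self, trials: pd.DataFrame, targets: dict, spec: ModelSpec,
                 enc_env: Environment, resolution: int, renormalize: bool,
                 env_factory):
        self.spec = spec
        self.renormalize = renormalize
        self.n_trials = len(trials)
        self._groups = []  # per (env, target): lines + s0 (+ S for renorm)
        self._S_cache: dict[tuple[str, str], tuple] = {}
        for (env_label, target_id), sub in trials.groupby(["environment", "target"],
                                                          sort=True):
            key = (str(env_label), str(target_id))
            if key not in self._S_cache:
                env = env_factory(str(env_label))
                grid = make_grid(env, resolution)
                f = prediction_field(targets[str(target_id)], enc_env, grid, spec,
                                     target_id=str(target_id))
                self._S_cache[key] = (f.S, grid)
            S, grid = self._S_cache[key]
            bins = np.array([point_to_bin(r, grid)
                             for r in sub[RESPONSE_COLS].to_numpy(float)])
            # canonical order: the fit must be exchangeable in trial order
            bins = bins[np.lexsort((bins[:, 2], bins[:, 1], bins[:, 0]))]
            i, j, k = bins[:, 0], bins[:, 1], bins[:, 2]
            lines = (S[:, j, k].T, S[i, :, k], S[i, j, :])
            s0 = S[i, j, k]
            self._groups.append((S, lines, s0, bins))

    def log_likelihoods(self, temperatures) -> np.ndarray:
        """Per-trial log-likelihood contributions at the given temperatures."""
        T = np.asarray(temperatures, dtype=float)
        out = []
        for S, lines, s0, bins in self._groups:
            if self.renormalize:
                log_p = log_probability_field(S, T, renormalize=True)
                ll = log_p[bins[:, 0], bins[:, 1], bins[:, 2]]
            else:
                ll = np.zeros_like(s0)
                for axis in range(3):
                    ll += s0 / T[axis] - logsumexp(lines[axis] / T[axis], axis=1)
            out.append(ll)
        if not out:
            return np.zeros(0)
        return np.maximum(np.concatenate(out), LOG_P_FLOOR)

    def total(self, temperatures) -> float:
        return float(self.log_likelihoods(temperatures).sum())


class PlacementModel(BaseEstimator):
    """Geometric encoding model with per-axis softmax temperatures.

    Parameters
    ----------
    model : {"fixed_distance", "fixed_ratio", "boundary_proximity", "ground_proximity"}
        Encoding model generating the prediction fields.
    targets : mapping or DataFrame
        Target label -> (x, y, z) coordinates in the encoding environment.
    c : float
        Proximity constant (metres) of the proximity models.
    resolution : int
        Baseline bins per axis; deformed axes scale with the deformation.
    renormalize : bool
        Globally renormalise P over the volume (off by default: the plain
        per-axis softmax product is used).
    n_starts : int
        Number of L-BFGS-B starts (1 at T = 1 plus fixed log-spaced extras).
    temp_bounds : (float, float)
        Box bounds on each temperature.
    tol : float
        Objective (ftol) convergence tolerance.

    Attributes
    ----------
    temperatures_ : ndarray (3,)
        Fitted (T_x, T_y, T_z).
    ll_ : float
        Summed baseline log-likelihood at the optimum.
    pseudo_r2_ : float
        Baseline pseudo-R² against the uniform-over-bins chance model.
    converged_, n_iter_ : optimiser diagnostics (best start).
    """

    #: log10 of the additional fixed multi-start temperatures.
    _EXTRA_STARTS_LOG10 = (-2.5, -1.5, -0.75, 0.5, 1.5)

    def __init__(self, model: str = "boundary_proximity", targets=None,
                 c: float = 1.5, resolution: int = 25, renormalize: bool = False,
                 n_starts: int = 6, temp_bounds: tuple = (1e-3, 1e3),
                 tol: float = 1e-6, base_length: float = 3.0,
                 stretch: float = 1.33, compress: float = 0.67):
        self.model = model
        self.targets = targets
        self.c = c
        self.resolution = resolution
        self.renormalize = renormalize
        self.n_starts = n_starts
        self.temp_bounds = temp_bounds
        self.tol = tol
        self.base_length = base_length
        self.stretch = stretch
        self.compress = compress

    # -- plumbing ---------------------------------------------------------
    def _spec(self) -> ModelSpec:
        return ModelSpec(self.model, self.c)

    def _env(self, label: str) -> Environment:
        return make_environment(label, base_length=self.base_length,
                                stretch=self.stretch, compress=self.compress)

    def _kernel(self, trials: pd.DataFrame) -> _LikelihoodKernel:
        return _LikelihoodKernel(trials, targets_to_dict(self.targets),
                                 self._spec(), self._env("baseline"),
                                 self.resolution, self.renormalize, self._env)

    def _validate_trials(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("trials must be a pandas DataFrame")
        missing = [c for c in ["environment", "target", *RESPONSE_COLS]
                   if c not in X.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        X = X.dropna(subset=RESPONSE_COLS)
        return X

    def chance_log_likelihood(self, X) -> float:
        """Summed LL of the uniform-over-bins chance model on trials X."""
        X = self._validate_trials(X)
        total = 0.0
        for env_label, sub in X.groupby("environment"):
            grid = make_grid(self._env(str(env_label)), self.resolution)
            total += len(sub) * -np.log(grid.n_bins)
        return total

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y=None):
        """Fit temperatures by maximum likelihood on baseline trials.

        ``X`` is one participant's baseline test-trial table.  The fit is
        deterministic: the multi-start list is fixed, and trial order does
        not affect the summed-likelihood objective.
        """
        if self.targets is None:
            raise ValueError("targets must be provided")
        X = self._validate_trials(X)
        if len(X) < 1:
            raise ValueError("no trials with responses to fit")
        kernel = self._kernel(X)

        lo, hi = self.temp_bounds
        bounds = [(np.log(lo), np.log(hi))] * 3
        starts = [np.zeros(3)]
        starts += [np.full(3, a * np.log(10.0)) for a in self._EXTRA_STARTS_LOG10]
        starts = starts[:max(1, int(self.n_starts))]

        def objective(log_t):
            return -kernel.total(np.exp(log_t))

        best = None
        any_converged = False
        for x0 in starts:
            res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": self.tol, "maxiter": 500})
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        self.temperatures_ = np.exp(best.x)
        self.ll_ = -float(best.fun)
        self.converged_ = any_converged
        self.n_iter_ = int(best.nit)
        self.n_trials_ = len(X)
        ll_chance = self.chance_log_likelihood(X)
        self.pseudo_r2_ = pseudo_r2(self.ll_, ll_chance)
        return self

    def log_likelihood(self, X) -> np.ndarray:
        """Per-trial log-likelihoods under the fitted temperatures."""
        self._check_fitted()
        X = self._validate_trials(X)
        if len(X) == 0:
            return np.zeros(0)
        return self._kernel(X).log_likelihoods(self.temperatures_)

    def score(self, X, y=None) -> float:
        """Summed log-likelihood of trials X (0.0 for an empty table)."""
        return float(self.log_likelihood(X).sum())

    def predict_field(self, target_id: str, environment: str = "baseline",
                      layer: str = "P") -> PredictionField:
        """Prediction field for a target in a test environment."""
        self._check_fitted()
        targets = targets_to_dict(self.targets)
        grid = make_grid(self._env(environment), self.resolution)
        return prediction_field(targets[str(target_id)], self._env("baseline"),
                                grid, self._spec(), temperatures=self.temperatures_,
                                renormalize=self.renormalize, target_id=str(target_id))

    def _check_fitted(self) -> None:
        if not hasattr(self, "temperatures_"):
            raise AttributeError("model is not fitted; call fit() first")


def fit_temperatures(trials, targets, spec: ModelSpec | str = "boundary_proximity",
                     resolution: int = 25, **kwargs) -> np.ndarray:
    """Functional wrapper: fitted (T_x, T_y, T_z) for one participant."""
    if isinstance(spec, ModelSpec):
        kwargs.setdefault("c", spec.c)
        model = spec.model
    else:
        model = spec
    est = PlacementModel(model=model, targets=targets, resolution=resolution, **kwargs)
    return est.fit(trials).temperatures_


def evaluate_deformed(est: PlacementModel, trials: pd.DataFrame) -> dict[str, float]:
    """Summed LL of deformed-environment trials, split by deformation plane."""
    out = {"horizontal": 0.0, "vertical": 0.0}
    trials = trials[trials["environment"] != "baseline"]
    for env_label, sub in trials.groupby("environment"):
        plane = DEFORMATION_AXIS_NAME[str(env_label)]
        out[plane] += est.score(sub)
    return out


def fit_cohort(trials: pd.DataFrame, targets, models=MODEL_IDS,
               phase: str = "test", **model_kwargs) -> pd.DataFrame:
    """Fit every model to every participant's baseline test trials.

    Returns one row per participant × model with fitted temperatures,
    baseline LL, deformed-plane LLs and pseudo-R² per condition.
    """
    trials = trials[trials["phase"] == phase] if "phase" in trials.columns else trials
    rows = []
    for pid, sub in trials.groupby("participant", sort=True):
        base = sub[sub["environment"] == "baseline"]
        deformed = sub[sub["environment"] != "baseline"]
        for model in models:
            est = PlacementModel(model=model, targets=targets, **model_kwargs)
            est.fit(base)
            ll_def = evaluate_deformed(est, deformed)
            row = {
                "participant": pid, "model": model,
                "T_x": est.temperatures_[0], "T_y": est.temperatures_[1],
                "T_z": est.temperatures_[2],
                "ll_baseline": est.ll_,
                "ll_horizontal": ll_def["horizontal"],
                "ll_vertical": ll_def["vertical"],
                "pseudo_r2_baseline": est.pseudo_r2_,
                "converged": est.converged_, "n_iter": est.n_iter_,
                "n_trials_baseline": est.n_trials_,
            }
            for plane in ("horizontal", "vertical"):
                plane_envs = [e for e, p in DEFORMATION_AXIS_NAME.items() if p == plane]
                sub_p = deformed[deformed["environment"].isin(plane_envs)]
                llc = est.chance_log_likelihood(sub_p) if len(sub_p) else 0.0
                row[f"pseudo_r2_{plane}"] = (pseudo_r2(ll_def[plane], llc)
                                             if llc != 0 else np.nan)
            rows.append(row)
    if "group" in trials.columns:
        groups = trials.groupby("participant")["group"].first()
        for row in rows:
            row["group"] = groups.loc[row["participant"]]
    return pd.DataFrame(rows)


def compare_models(fits: pd.DataFrame,
                   conditions=("horizontal", "vertical")) -> dict[str, pd.DataFrame]:
    """Rank models per participant and run group-level paired comparisons.

    Returns ``{"per_participant": ..., "pairwise": ...}``.  The per-
    participant table reports each model's LL and the best model per
    condition (ties are reported as "tie").  Pairwise paired t-tests are
    Bonferroni-corrected over all model pairs × conditions; with a single
    participant no tests are run.
    """
    models = sorted(fits["model"].unique())
    counts = fits.groupby("participant")["model"].nunique()
    if counts.nunique() > 1 or counts.iloc[0] != len(models):
        raise ValueError("unbalanced input: every participant needs every model")

    per_rows = []
    for pid, sub in fits.groupby("participant", sort=True):
        for cond in conditions:
            col = f"ll_{cond}"
            lls = sub.set_index("model")[col]
            best_ll = lls.max()
            winners = lls.index[np.isclose(lls, best_ll, rtol=0, atol=1e-12)]
            row = {"participant": pid, "condition": cond,
                   "best_model": winners[0] if len(winners) == 1 else "tie"}
            row.update({f"ll_{m}": lls[m] for m in models})
            per_rows.append(row)
    per_participant = pd.DataFrame(per_rows)

    pair_rows = []
    n_participants = fits["participant"].nunique()
    pairs = list(itertools.combinations(models, 2))
    n_tests = len(pairs) * len(conditions)
    for cond in conditions:
        wide = fits.pivot(index="participant", columns="model", values=f"ll_{cond}")
        for a, b in pairs:
            diff = wide[a] - wide[b]
            if n_participants > 1 and diff.std(ddof=1) > 0:
                t, p = ttest_rel(wide[a], wide[b])
                p_adj = min(1.0, p * n_tests)
            else:
                t, p, p_adj = np.nan, np.nan, np.nan
            pair_rows.append({"condition": cond, "model_a": a, "model_b": b,
                              "mean_diff": float(diff.mean()), "t": t,
                              "p": p, "p_bonferroni": p_adj,
                              "n": n_participants})
    return {"per_participant": per_participant, "pairwise": pd.DataFrame(pair_rows)}
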
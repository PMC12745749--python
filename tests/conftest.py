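"""Shared fixtures.

The expensive simulation-plus-fitting fixtures are session-scoped so the
model-identification results are computed once and reused by the unit and
acceptance tests.
"""

from __future__ import annotations

import pandas as pd
import pytest

from volmem import fitting, simulate
from volmem.models import MODEL_IDS
from volmem.simulate import GenerativeProfile


@pytest.fixture(scope="session")
def targets():
    return simulate.generate_targets(seed=11)


@pytest.fixture(scope="session")
def cohort():
    """Small default cohort (all four group profiles), trials + targets."""
    trials, targets = simulate.simulate_cohort(n_per_group=8, seed=13)
    return trials, targets


@pytest.fixture(scope="session")
def identification(targets):
    """Fit all four models to cohorts simulated from each generative model.

    13 simulated participants per generative model (52 total), 90 test
    trials each, identical design and temperatures; selection is by summed
    log-likelihood on the deformed-environment trials after fitting
    temperatures on baseline.  Returns a tidy DataFrame with one row per
    participant x candidate model plus the generative model and winner.
    """
    n_per_model = 13
    rows = []
    for gen in MODEL_IDS:
        profile = GenerativeProfile("sim", "flying", "stretch", gen,
                                    (0.02, 0.02, 0.03))
        for i in range(n_per_model):
            pid = f"{gen}_{i:02d}"
            design = simulate.generate_design(profile, targets,
                                              seed=1000 + i, participant=pid)
            trials = simulate.simulate_responses(design, profile, targets,
                                                 seed=2000 + i)
            test = trials[trials["phase"] == "test"]
            base = test[test["environment"] == "baseline"]
            deformed = test[test["environment"] != "baseline"]
            scores = {}
            planes = {}
            for model in MODEL_IDS:
                est = fitting.PlacementModel(model=model, targets=targets)
                est.fit(base)
                ll = fitting.evaluate_deformed(est, deformed)
                scores[model] = ll["horizontal"] + ll["vertical"]
                planes[model] = ll
            winner = max(scores, key=scores.get)
            for model, ll in scores.items():
                rows.append({"generative": gen, "participant": pid,
                             "model": model, "ll_deformed": ll,
                             "ll_horizontal": planes[model]["horizontal"],
                             "ll_vertical": planes[model]["vertical"],
                             "winner": winner})
    return pd.DataFrame(rows)
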
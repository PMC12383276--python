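"""Shared fixtures: small synthetic data sets and session-scoped model fits.

MCMC fits are expensive, so fits exercised by several tests (the gamma and
bernoulli GAMMs) are built once per session and shared read-only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nutflex.simulate import (
    SimConfig,
    make_truth,
    simulate_follows,
    simulate_phenology,
    simulate_urine,
)

SMALL = SimConfig(
    n_individuals=12,
    n_months=36,
    trees_per_plot=400,
    follows_per_individual=25,
    urine_match_fraction=0.8,
    miss_cpeptide=0.3,
    miss_urea=0.1,
    miss_d15n=0.5,
    miss_ketone=0.1,
)


@pytest.fixture(scope="session")
def truth_partial():
    return make_truth("partial_prioritization", 7)


@pytest.fixture(scope="session")
def small_tables(truth_partial):
    phen = simulate_phenology(SMALL, truth_partial)
    follows = simulate_follows(SMALL, truth_partial, phen)
    urine = simulate_urine(follows, truth_partial, SMALL)
    return {"phenology": phen, "follows": follows, "urine": urine}


@pytest.fixture(scope="session")
def gamma_gamm_fit():
    """Gamma-family GAMM on a known sinusoidal log-mean (shared across tests)."""
    from nutflex.gam import BayesGAMM

    rng = np.random.default_rng(7)
    n, J = 600, 8
    x = rng.uniform(0.0, 10.0, n)
    ids = rng.integers(0, J, n)
    re = rng.normal(0.0, 0.3, J)
    y = rng.gamma(5.0, np.exp(1.0 + 0.5 * np.sin(x) + re[ids]) / 5.0)
    df = pd.DataFrame({"y": y, "x": x, "individual_id": [f"I{i}" for i in ids]})
    model = BayesGAMM(df, "y", "x", "gamma", k=8)
    res = model.fit(profile="test", seed=1)
    return {"model": model, "results": res, "truth_fn": lambda g: 0.5 * np.sin(g)}


@pytest.fixture(scope="session")
def bernoulli_gamm_fit():
    """Bernoulli GAMM with a monotone-decreasing logit truth (shared)."""
    from nutflex.gam import BayesGAMM

    rng = np.random.default_rng(11)
    n, J = 600, 8
    x = rng.uniform(0.0, 10.0, n)
    ids = rng.integers(0, J, n)
    p = 1.0 / (1.0 + np.exp(-(-0.5 - 0.8 * (x - 5.0))))
    y = (rng.random(n) < p).astype(float)
    df = pd.DataFrame({"y": y, "x": x, "individual_id": [f"I{i}" for i in ids]})
    model = BayesGAMM(df, "y", "x", "bernoulli", k=8)
    res = model.fit(profile="test", seed=2)
    return {"model": model, "results": res}
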
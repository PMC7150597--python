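"""Shared fixtures: small synthetic datasets and independent oracles."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import afcost
from afcost.cohort import derive_covariates_from_records
from afcost.design import DesignSpec


def degenerate_marginals(**overrides) -> dict:
    """All probability mass on the reference category of every covariate."""
    m = {
        "sex": {"male": 1.0},
        "simd": {1: 1.0},
        "geography": {"large_urban": 1.0},
        "health_board": {"greater_glasgow_and_clyde": 1.0},
        "comorbidity": {1: 1.0},
        "died_within_5y": {False: 1.0},
        "age_group": {"0-49": 1.0},
        "admission_year": {2005: 1.0},
    }
    m.update(overrides)
    return m


def intercept_only_params(
    beta0: float,
    gamma0: float,
    shape: float = 2.0,
    seed: int = 0,
    sector_split=(0.79, 0.08, 0.07, 0.06),
) -> afcost.DGPParams:
    """A DGP whose index reduces to the intercepts (reference-only population)."""
    spec = DesignSpec(blocks=("sex",), year_center=None)
    return afcost.DGPParams(
        beta=np.array([beta0, 0.0]),
        gamma_coef=np.array([gamma0, 0.0]),
        gamma_shape=shape,
        sector_split=sector_split,
        marginals=degenerate_marginals(),
        seed=seed,
        design=spec,
    )


def grid_maximise(loglik, n_params: int = 2, lo: float = -3.0, hi: float = 3.0,
                  grid: int = 21, levels: int = 8) -> np.ndarray:
    """Coarse-to-fine grid search maximiser (independent likelihood oracle)."""
    lo = np.full(n_params, float(lo))
    hi = np.full(n_params, float(hi))
    best = None
    for _ in range(levels):
        axes = [np.linspace(lo[i], hi[i], grid) for i in range(n_params)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, n_params)
        vals = np.array([loglik(t) for t in mesh])
        best = mesh[int(np.argmax(vals))]
        step = (hi - lo) / (grid - 1)
        lo, hi = best - step, best + step
    return best


@pytest.fixture(scope="session")
def default_params() -> afcost.DGPParams:
    return afcost.default_dgp_params(seed=42)


@pytest.fixture(scope="session")
def small_bundle(default_params):
    pop = afcost.generate_population(250, default_params)
    bundle = afcost.generate_linked_records(pop, default_params)
    return pop, bundle


@pytest.fixture(scope="session")
def costed_roundtrip(small_bundle, default_params):
    """Records regenerated through the full clean→cohort→cost path."""
    pop, bundle = small_bundle
    episodes = afcost.clean_episodes(bundle.episodes)
    index_events = afcost.identify_incident_af(episodes)
    covariates = derive_covariates_from_records(episodes, index_events, pop)
    skeleton = afcost.build_panel(index_events, covariates, bundle.deaths)
    costed = afcost.aggregate_to_panel(
        skeleton, replace(bundle, episodes=episodes), bundle.tariffs
    )
    return {
        "population": pop,
        "bundle": bundle,
        "episodes": episodes,
        "index_events": index_events,
        "covariates": covariates,
        "panel": costed,
        "truth": bundle.truth_panel,
    }


@pytest.fixture(scope="session")
def model_panel():
    """A moderate panel for model fits: reduced design, 1500 patients."""
    spec = DesignSpec(blocks=("sex", "comorbidity", "mortality"), year_center=None)
    params = afcost.default_dgp_params(seed=7, design=spec)
    pop = afcost.generate_population(1500, params)
    panel = afcost.generate_panel(pop, params)
    return params, panel
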
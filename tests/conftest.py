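"""Shared fixtures: the small synthetic study and one full calibration.

The expensive artefacts (mortality table, surveys, raked cells, and the
end-to-end fit of the selected variant) are session-scoped so the recovery,
trend and predictive-check tests share one computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from smoketrends.calibrate import fit_variant
from smoketrends.inference import McmcConfig
from smoketrends.likelihood import LikelihoodConfig
from smoketrends.surveys import CellConfig, add_age_bands, build_cells, rake_weights
from smoketrends.synthetic import (
    Scenario,
    make_hr_study,
    make_mortality,
    make_surveys,
    make_truth,
)
from smoketrends.variants import variant_ladder

#: Reference grid for truth-recovery checks: decades across the range the
#: surveys inform, and quit-rate points echoing the ages/years the trend
#: tables report.
RECOVERY_BIRTH_YEARS = (1920, 1940, 1960, 1980)
RECOVERY_QUIT_POINTS = ((30, 1980), (50, 1990), (50, 2016), (70, 2000))
FIT_SEED = 20260929


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    return Scenario.small()


@pytest.fixture(scope="session")
def truth(small_scenario):
    return make_truth(small_scenario)


@pytest.fixture(scope="session")
def mort(truth):
    return make_mortality(truth)


@pytest.fixture(scope="session")
def hr_prior(truth):
    return make_hr_study(truth)


@pytest.fixture(scope="session")
def survey_data(truth, mort):
    return make_surveys(truth, mort)


@pytest.fixture(scope="session")
def raked_weights(survey_data):
    table, margins = survey_data
    banded = add_age_bands(table)
    w = np.empty(len(banded))
    for _, group in banded.groupby("survey_id", sort=False):
        w[group.index] = rake_weights(group, margins)
    return w


@pytest.fixture(scope="session")
def cells(survey_data, raked_weights):
    table, _ = survey_data
    return build_cells(table, raked_weights, CellConfig(age_group_width=5))


@pytest.fixture(scope="session")
def selected_variant():
    return variant_ladder()[5]  # rung F


@pytest.fixture(scope="session")
def small_fit(cells, mort, hr_prior, selected_variant):
    """Full calibration of the selected variant on the small study:
    2 chains, 400 burn-in sweeps, sampling capped at 2000 sweeps."""
    return fit_variant(
        cells, mort, hr_prior, selected_variant, seed=FIT_SEED,
        mcmc=McmcConfig(burn_in=400, target_ess=50.0, check_every=400,
                        max_sweeps=2000),
        n_chains=2,
    )


def fast_scenario(seed: int, **overrides) -> Scenario:
    """Small-study scenario at 4 substeps/year for replicate loops."""
    return dataclasses.replace(Scenario.small(**overrides), substeps=4,
                               seed=seed)


FAST_LIK = LikelihoodConfig(substeps=4)
FAST_MCMC = McmcConfig(burn_in=200, target_ess=50.0, check_every=600,
                       max_sweeps=600)


def make_replicate_data(seed: int):
    """One seed-replicate of the small study (4 substeps/year)."""
    sc = fast_scenario(seed)
    tr = make_truth(sc)
    m = make_mortality(tr)
    hr = make_hr_study(tr)
    table, margins = make_surveys(tr, m)
    banded = add_age_bands(table)
    w = np.empty(len(banded))
    for _, g in banded.groupby("survey_id", sort=False):
        w[g.index] = rake_weights(g, margins)
    c = build_cells(table, w, CellConfig(age_group_width=5))
    return tr, m, hr, c


def fit_replicate(cells_, mort_, hr_, variant, seed: int):
    return fit_variant(cells_, mort_, hr_, variant, seed=seed,
                       lik_config=FAST_LIK, mcmc=FAST_MCMC, n_chains=2,
                       map_maxiter=600)


@pytest.fixture(scope="session")
def replicate_fits():
    """Twelve seed-replicates of the small study, each with the selected
    variant fitted at reduced chain length; shared by the interval-
    calibration and model-selection checks."""
    out = []
    for rep in range(12):
        seed = 3000 + 17 * rep
        tr, m, hr, c = make_replicate_data(seed)
        out.append((tr, m, hr, c,
                    fit_replicate(c, m, hr, variant_ladder()[5], seed + 1)))
    return out
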
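"""Shared fixtures: substitution models, toy germlines, small repertoires."""

import pytest

from repclust.backtranslation import aggregate_fivemer_to_trimer
from repclust.shm_calibration import RateTiers
from repclust.synthetic_repertoire import (
    SimConfig,
    default_fivemer_model,
    make_study_fixture,
    simulate_repertoire,
    toy_heavy_references,
)


@pytest.fixture(scope="session")
def fivemer_model():
    return default_fivemer_model(seed=0)


@pytest.fixture(scope="session")
def trimer_model(fivemer_model):
    return aggregate_fivemer_to_trimer(fivemer_model)


@pytest.fixture(scope="session")
def heavy_refs():
    return toy_heavy_references()


@pytest.fixture(scope="session")
def study_fixture():
    """(epitopes, records): the 54-antibody curated-set fixture."""
    return make_study_fixture(seed=0)


@pytest.fixture(scope="session")
def small_repertoire(trimer_model):
    """300 simulated sequences with per-sequence metadata."""
    config = SimConfig(n_sequences=300, seed=11, rate_tiers=RateTiers())
    return simulate_repertoire(config, trimer_model, return_meta=True)
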
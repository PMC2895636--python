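import numpy as np
import pytest

import condcorr as cc
from condcorr.database import Population


@pytest.fixture(scope="session")
def model():
    return cc.load_default_model()


@pytest.fixture(scope="session")
def short_sim_cfg():
    """Fast integration settings for behavioural (non-metric) tests."""
    return cc.SimulationConfig(dt=0.05, total_duration=600.0, transient_discard=200.0)


@pytest.fixture(scope="session")
def planted_db():
    """50k-model surrogate database with one planted positive pair."""
    spec = cc.PlantedDatabaseSpec(
        n_models=50_000,
        planted={"periodic_bursting": [(("CaS", "KCa"), "+", 1, 0.8)]},
        seed=11,
    )
    return cc.make_planted_db(spec)


@pytest.fixture(scope="session")
def null_db():
    """Surrogate database whose conductances are independent of type."""
    spec = cc.PlantedDatabaseSpec(n_models=30_000, seed=12)
    return cc.make_planted_db(spec)


def class_population(db, activity_class, label=None):
    return Population(
        label or f"all {activity_class}",
        np.nonzero(db.class_mask(activity_class))[0],
    )


@pytest.fixture(scope="session")
def burster_pop(planted_db):
    return class_population(planted_db, "periodic_bursting")
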
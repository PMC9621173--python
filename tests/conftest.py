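import warnings

import pytest

from hesaudit.codesets import condition_specs
from hesaudit.data_model import build_spells
from hesaudit.pipeline import audit_tables
from hesaudit.synthetic import GeneratorConfig, fixture_small, generate_population


@pytest.fixture(scope="session")
def fixture_tables():
    """The hand-enumerated small fixture: (patients, episodes, expected)."""
    return fixture_small()


@pytest.fixture(scope="session")
def fixture_spells(fixture_tables):
    _, episodes, _ = fixture_tables
    return build_spells(episodes)


@pytest.fixture(scope="session")
def specs():
    return condition_specs()


@pytest.fixture(scope="session")
def small_population():
    """A modest synthetic population shared across tests (seed fixed)."""
    cfg = GeneratorConfig(
        n_patients={"autism": 250, "dmpc": 250, "pdd": 150}, seed=7
    )
    return cfg, generate_population(cfg)


@pytest.fixture(scope="session")
def audited_autism(small_population):
    """Full pipeline result on the shared population (autism cohort)."""
    _, (patients, episodes, _) = small_population
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return audit_tables(
            patients, episodes, "autism", seed=7, n_iter=1,
            grid={"n_estimators": [60], "max_depth": [6],
                  "min_samples_leaf": [10], "class_weight": [None]},
            max_attribution_rows=150,
        )
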
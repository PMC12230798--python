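import dataclasses

import pytest

from lupine_ipm import (
    GeneratorSpec,
    IPMConfig,
    canonical_table,
    default_size_limits,
    simulate_field_fecundity,
    simulate_greenhouse,
)
from lupine_ipm.synthetic import FIELD_DEFAULTS


@pytest.fixture(scope="session")
def canonical():
    """Published parameter sets keyed by (origin, treatment)."""
    return canonical_table()


@pytest.fixture(scope="session")
def resolved_config(canonical):
    """Default IPM config with canonical fallback size limits resolved."""
    cfg = IPMConfig()
    L, U = default_size_limits(canonical, cfg)
    return dataclasses.replace(cfg, L=L, U=U)


@pytest.fixture(scope="session")
def greenhouse_df(canonical):
    """Study-sized synthetic greenhouse dataset (55 individuals per cell)."""
    return simulate_greenhouse(GeneratorSpec(params=canonical, seed=5, n_per_cell=55))


@pytest.fixture(scope="session")
def field_by_origin():
    """Synthetic field fecundity records per origin, calibrated to 79 / 42."""
    return {
        origin: simulate_field_fecundity(
            pod_mean, seed_mean, rng_seed=100 + i, population_prefix=f"{origin}_pop"
        )
        for i, (origin, (pod_mean, seed_mean)) in enumerate(sorted(FIELD_DEFAULTS.items()))
    }
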
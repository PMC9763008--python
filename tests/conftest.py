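"""Shared fixtures: small, fast experiment configurations."""

import numpy as np
import pytest

from eebae.simulation import ExperimentConfig


def make_gaf_config(**overrides) -> ExperimentConfig:
    """A small gap-acceptance experiment that runs in milliseconds."""
    base = dict(
        model="gaf",
        param_ranges={"t_cr": (5, 10), "sigma": (1, 4)},
        param_grid_sizes={"t_cr": 10, "sigma": 10},
        stim_ranges={"gap": (4, 12)},
        stim_grid_sizes={"gap": 9},
        truth={"t_cr": 7.3, "sigma": 2.2804},
        policy={"kind": "ee", "epsilon": 4.0, "trials": 40},
        replications=5,
        seed=7,
    )
    policy = base.pop("policy")
    policy.update(overrides.pop("policy", {}))
    base.update(overrides)
    base["policy"] = policy
    return ExperimentConfig.model_validate(base)


@pytest.fixture
def small_gaf():
    return make_gaf_config()


@pytest.fixture
def rng():
    return np.random.default_rng(20220701)
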
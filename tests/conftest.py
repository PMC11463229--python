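import numpy as np
import pytest

from sorsim import ModelConfig, PopulationState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_config():
    """Factory for configs with all processes off unless overridden."""

    def _make(**overrides):
        base = dict(
            N=10,
            lambda_stim=0.0,
            beta=0.0,
            gamma=0.0,
            delta=0.0,
            mu=0.0,
            epsilon=0.0,
            p_beneficial=1.0,
            p_neutral=0.0,
            p_deleterious=0.0,
            t_max=100.0,
            sample_dt=10.0,
            seed=0,
        )
        base.update(overrides)
        return ModelConfig.model_validate(base)

    return _make


@pytest.fixture
def seeded_state():
    """Factory: a fresh state with one beneficial product in entity 0."""

    def _make(n=10, effect_size=0.1, n_holders=1, effect_class="beneficial"):
        state = PopulationState(n)
        state.create_product(0, effect_class, effect_size, parent_id=None)
        for eid in range(1, n_holders):
            state.add_product(eid, 0)
        return state

    return _make
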
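import hypothesis
import numpy as np
import pytest

import sparsepool as sp

hypothesis.settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_family() -> sp.PatternSet:
    """3-class prototype family, 120 bits at density 0.15, 10 samples/class."""
    protos = sp.generate_prototypes(3, 120, 0.15, seed=11)
    return sp.sample_family(protos, 10, 10.0, seed=12)


@pytest.fixture(scope="session")
def small_config() -> sp.SPConfig:
    return sp.SPConfig(
        n_inputs=120, n_columns=64, column_activation_pct=10.0, seed=3
    )


@pytest.fixture()
def small_state(small_config) -> sp.SPState:
    return sp.init_pooler(small_config)


@pytest.fixture()
def trained_small(small_config, tiny_family) -> sp.SPState:
    state = sp.init_pooler(small_config)
    return sp.fit(state, tiny_family, 5)
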
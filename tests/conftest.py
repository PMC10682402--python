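import dataclasses

import pytest

from yeastrls import AgingSimParams, WeibullParams


@pytest.fixture
def default_params() -> WeibullParams:
    """A realistic wild-type-like survival law (mean ~22.7 generations)."""
    return WeibullParams(r=0.04, alpha=4.0)


@pytest.fixture
def default_sim(default_params) -> AgingSimParams:
    """The standard screen design: 200 cells, two replicates, 72 h."""
    return AgingSimParams(true_params=default_params, seed=20230)


@pytest.fixture
def reseed():
    """Return a copy of an AgingSimParams with a different seed."""

    def _reseed(params: AgingSimParams, seed: int) -> AgingSimParams:
        return dataclasses.replace(params, seed=seed)

    return _reseed
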
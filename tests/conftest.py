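import dataclasses

import pytest
from hypothesis import settings

import qimshelf as q

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    """The bundled whole-king-weakfish demerit protocol."""
    return q.load_protocol()


@pytest.fixture(scope="session")
def default_cfg():
    return q.default_config(seed=7)


@pytest.fixture(scope="session")
def noiseless_cfg(default_cfg):
    models = {
        name: dataclasses.replace(m, noise_sd=0.0)
        for name, m in default_cfg.indicator_models.items()
    }
    return dataclasses.replace(
        default_cfg, referee_noise_sd=0.0, indicator_models=models
    )


@pytest.fixture(scope="session")
def study(protocol, default_cfg):
    return q.simulate_study(default_cfg, protocol)


def make_sheet(protocol, day=1.0, fill=0, overrides=None, lot="L", fish="F1", ref="R1"):
    """A complete sheet with every parameter at `fill` (clamped to its max),
    selected parameters overridden."""
    scores = {
        p.parameter_name: min(fill, p.max_demerit) for p in protocol.parameters
    }
    scores.update(overrides or {})
    return q.Assessment(
        lot=lot, fish_id=fish, referee_id=ref, storage_day=day, scores=scores
    )


@pytest.fixture
def sheet_factory(protocol):
    return lambda **kw: make_sheet(protocol, **kw)
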
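import dataclasses

import pytest

from pparscreen.config import SimConfig


@pytest.fixture
def small_sim() -> SimConfig:
    """A small, fast configuration with no injected effects."""
    return SimConfig(seed=1, n_genes=20, n_affected_down=0, n_affected_up=0)


@pytest.fixture
def null_sim() -> SimConfig:
    """Null configuration at realistic scale: no effect, unit library scale."""
    return SimConfig(seed=7, n_genes=2000, n_affected_down=0, n_affected_up=0,
                     library_scale=1.0)


def replace(cfg: SimConfig, **kwargs) -> SimConfig:
    return dataclasses.replace(cfg, **kwargs)
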
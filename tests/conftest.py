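import numpy as np
import pytest

from nicheshift.env_data import EnvStack
from nicheshift.synthetic_data import SyntheticConfig, make_scenario


@pytest.fixture
def tiny_stack() -> EnvStack:
    """5x4 stack with layer values equal to simple functions of (row, col)."""
    nrows, ncols = 5, 4
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    layers = {
        "a": rr.astype(float),
        "b": cc.astype(float),
        "c": (10 * rr + cc).astype(float),
    }
    mask = np.ones((nrows, ncols), dtype=bool)
    mask[0, 0] = False  # one inaccessible cell
    return EnvStack(layers, mask, xll=0.0, yll=0.0, cell_size=1.0)


_SCENARIOS: dict = {}


@pytest.fixture
def scenario_factory():
    """Session-cached small paired-range scenarios keyed by (shift, seed)."""

    def make(shift: float = 0.0, seed: int = 0, **overrides):
        key = (shift, seed, tuple(sorted(overrides.items())))
        if key not in _SCENARIOS:
            cfg = SyntheticConfig(
                shape=(60, 60),
                n_native=50,
                n_invasive=200,
                n_background=1000,
                shift_sigma=shift,
                seed=seed,
                **overrides,
            )
            _SCENARIOS[key] = make_scenario(cfg)
        return _SCENARIOS[key]

    return make
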
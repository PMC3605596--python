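import numpy as np
import pytest

from tirftrack.simulate import MovieConfig, simulate_movie


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_movie():
    """A small tracked-density movie reused by io/tracking tests."""
    cfg = MovieConfig(field_width=10.0, field_height=10.0, n_frames=40,
                      receptor_density=0.3, d_lat=0.15, bleach_rate=0.0,
                      rng_seed=42)
    stack, gt = simulate_movie(cfg)
    return cfg, stack, gt


@pytest.fixture(scope="session")
def single_spot_movie():
    """One immobile, non-bleaching emitter well inside a small field."""
    for seed in range(200, 260):
        cfg = MovieConfig(field_width=3.0, field_height=3.0, n_frames=10,
                          receptor_density=1 / 9.0, d_lat=0.0,
                          bleach_rate=0.0, rng_seed=seed)
        stack, gt = simulate_movie(cfg)
        p = gt.data.iloc[0]
        if 0.8 < p.x_um < 2.2 and 0.8 < p.y_um < 2.2:
            return cfg, stack, gt
    raise RuntimeError("no centered single-spot movie found")
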
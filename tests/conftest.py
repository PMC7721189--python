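import numpy as np
import pytest

from spatialscaling import CitySystem, DistanceMatrix


def make_random_system(rng, n=12, total_tokens=10_000, box=(-10.0, 10.0, -10.0, 10.0),
                       with_counts=True):
    """Small random system: lognormal populations, per-capita counts."""
    lat = rng.uniform(box[0], box[1], n)
    lon = rng.uniform(box[2], box[3], n)
    x = np.ceil(rng.lognormal(np.log(1e3), 1.0, n))
    y = None
    if with_counts:
        y = rng.multinomial(total_tokens, x / x.sum()).astype(float)
    return CitySystem(unit_id=[f"u{i:03d}" for i in range(n)], x=x, y=y,
                      lat=lat, lon=lon)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_unit_system():
    """The hand-worked pair: populations (100, 300) at 10 km separation."""
    system = CitySystem(unit_id=["a", "b"], x=[100.0, 300.0], y=[1.0, 1.0])
    dist = DistanceMatrix([[0.0, 10.0], [10.0, 0.0]])
    return system, dist


@pytest.fixture
def random_system(rng):
    return make_random_system(rng)
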
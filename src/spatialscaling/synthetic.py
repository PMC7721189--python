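"""Synthetic city systems and model-drawn token counts.

The generator emulates the shape of national municipal data: heavy-tailed
populations (Pareto/"zipf-like" or lognormal), unit centroids scattered over
a continental bounding box, and token counts drawn from the generative
allocation model at chosen (family, alpha, beta, Y).  Defaults mirror the
regimes where the method operates in practice: a couple of hundred units on
a ~2000 km box, 1e6-1e7 tokens, interaction scales of tens of km.

Everything is driven by a single integer seed, so a configuration fully
determines its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np

from .city_system import CitySystem, DistanceMatrix
from .interaction import Kernel, attractiveness
from .likelihood import token_probabilities


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-data generator.

    ``pop_law`` is ``"zipf"`` (Pareto tail with exponent ``zipf_exponent``,
    minimum ``pop_scale`` inhabitants, capped at ``pop_cap``) or
    ``"lognormal"``.  ``region`` is a (lat_min, lat_max, lon_min, lon_max)
    bounding box in decimal degrees; the default spans roughly 2000 x 2000 km
    near the equator.  ``family``/``alpha``/``beta`` select the allocation
    model used to draw the ``total_tokens`` counts.
    """

    n_units: int = 200
    pop_law: str = "zipf"
    zipf_exponent: float = 2.0
    pop_scale: float = 1_000.0
    pop_cap: float = 1e7
    lognormal_mean_log: float = 9.2
    lognormal_sigma_log: float = 1.5
    region: Tuple[float, float, float, float] = (-18.0, 0.0, -54.0, -36.0)
    total_tokens: int = 1_000_000
    family: str = "G"
    alpha: float = 20.0
    beta: float = 1.2
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_populations(config: GeneratorConfig, rng: np.random.Generator,
                        n: int) -> np.ndarray:
    if config.pop_law == "zipf":
        u = rng.uniform(size=n)
        pops = config.pop_scale * u ** (-1.0 / (config.zipf_exponent - 1.0))
        pops = np.minimum(pops, config.pop_cap)
    elif config.pop_law == "lognormal":
        pops = rng.lognormal(config.lognormal_mean_log,
                             config.lognormal_sigma_log, size=n)
    else:
        raise ValueError(f"unknown pop_law {config.pop_law!r}")
    return np.maximum(np.ceil(pops), 1.0)


def sample_city_system(config: GeneratorConfig,
                       rng: Optional[np.random.Generator] = None) -> CitySystem:
    """Draw unit centroids and populations (no counts attached yet)."""
    if config.n_units < 2:
        raise ValueError("need at least 2 units")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lat_min, lat_max, lon_min, lon_max = config.region
    lat = rng.uniform(lat_min, lat_max, size=config.n_units)
    lon = rng.uniform(lon_min, lon_max, size=config.n_units)
    x = _sample_populations(config, rng, config.n_units)
    unit_id = np.array([f"u{i:04d}" for i in range(config.n_units)], dtype=object)
    return CitySystem(unit_id=unit_id, x=x, y=None, lat=lat, lon=lon)


def sample_tokens(system: CitySystem, distance: Optional[DistanceMatrix],
                  family: str, alpha: float, beta: float, total_tokens: int,
                  seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One city-level multinomial draw of Y tokens from the allocation model.

    Sampling at city level is exact under the model: individuals within a
    unit are exchangeable, so the per-person process aggregates to a single
    Multinomial(Y, p_c).  ``family`` may be "P" (per-capita, beta = 1 with
    no kernel) or one of "C", "G", "E".
    """
    total_tokens = int(total_tokens)
    if total_tokens < 1:
        raise ValueError("total_tokens must be at least 1")
    family = str(family).upper()
    if family == "P":
        p = system.x / system.total_population
    else:
        A = attractiveness(system, distance, Kernel(family, alpha))
        p = token_probabilities(system.x, A, beta)
    rng = rng if rng is not None else np.random.default_rng(seed)
    return rng.multinomial(total_tokens, p).astype(float)


def simulate(config: GeneratorConfig) -> Tuple[CitySystem, DistanceMatrix]:
    """Full pipeline: sample a city system, its distances, and its counts."""
    rng = np.random.default_rng(config.seed)
    system = sample_city_system(config, rng=rng)
    distance = DistanceMatrix.from_system(system)
    y = sample_tokens(system, distance, config.family, config.alpha, config.beta,
                      config.total_tokens, rng=rng)
    return system.with_counts(y), distance
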
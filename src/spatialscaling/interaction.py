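"""Pairwise interaction kernels a(d; alpha) and the per-unit attractiveness A_i.

Three kernel families are supported, all normalised to a(0) = 1 and
monotonically non-increasing in distance:

* ``C`` (city): interactions occur only at distance zero, a(d) = delta(d).
* ``G`` (gravitational): a(d) = 1 / (1 + (d/alpha)^2), a Lorentzian decay.
* ``E`` (exponential): a(d) = exp(-d ln2 / alpha).

For G and E the scale ``alpha`` (km) is the half-decay distance:
a(alpha; alpha) = 1/2.  As alpha -> 0 both reduce to the C kernel (alpha = 0
is mapped to C exactly); as alpha -> infinity every pair interacts fully and
the per-capita model is recovered downstream.

The attractiveness of an individual in unit i is the kernel-weighted sum of
all populations, A_i = sum_i' x_i' a(d_ii'), including the own-unit term
x_i a(0) = x_i; hence A_i >= x_i always, with equality for the C kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .city_system import CitySystem, DistanceMatrix

KERNEL_FAMILIES = ("C", "G", "E")
_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class Kernel:
    """Interaction kernel family with half-decay scale ``alpha`` in km.

    ``alpha`` is ignored for the C family.  Passing ``alpha = 0`` to G or E
    selects the C kernel exactly (their pointwise limit when all off-diagonal
    distances are positive), avoiding a 0/0 in the kernel formulas.
    """

    family: str
    alpha: float = 0.0

    def __post_init__(self) -> None:
        fam = str(self.family).upper()
        if fam not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; use one of {KERNEL_FAMILIES}")
        object.__setattr__(self, "family", fam)
        alpha = float(self.alpha)
        if not alpha >= 0:
            raise ValueError("alpha must be non-negative")
        object.__setattr__(self, "alpha", alpha)

    @property
    def effective_family(self) -> str:
        """Family actually applied: G/E with alpha = 0 degenerate to C."""
        if self.family in ("G", "E") and self.alpha == 0.0:
            return "C"
        return self.family

    def __call__(self, d) -> np.ndarray:
        """Evaluate a(d; alpha) elementwise; result is in [0, 1]."""
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        fam = self.effective_family
        if fam == "C":
            return (d == 0).astype(float)
        if fam == "G":
            r = d / self.alpha
            return 1.0 / (1.0 + r * r)
        # E
        return np.exp(-d * _LN2 / self.alpha)


def kernel_value(kernel: Kernel, d) -> np.ndarray:
    """Interaction weight a(d; alpha) for the given kernel."""
    return kernel(d)


def attractiveness(system: CitySystem, distance: DistanceMatrix | None,
                   kernel: Kernel) -> np.ndarray:
    """Per-unit attractiveness A_i = sum_i' x_i' a(d_ii'; alpha).

    The C kernel needs no distance matrix (A = x up to co-located units;
    with a distance matrix, distinct units at distance zero interact fully —
    the kernel keys on d = 0, not on unit identity).
    """
    x = system.x
    if distance is None:
        if kernel.effective_family != "C":
            raise ValueError("a distance matrix is required for the G and E kernels")
        return x.copy()
    if distance.n_units != system.n_units:
        raise ValueError("distance matrix size does not match the number of units")
    return kernel(distance.values) @ x


def attractiveness_ratio(system: CitySystem, distance: DistanceMatrix | None,
                         kernel: Kernel) -> np.ndarray:
    """Elementwise A_i / x_i (>= 1): the boost in effective interactions
    relative to a unit in isolation; identically 1 for the C kernel."""
    return attractiveness(system, distance, kernel) / system.x


def attractiveness_table(system: CitySystem, distance: DistanceMatrix | None,
                         kernel: Kernel):
    """Tidy per-unit table (unit_id, x, A, A_over_x) for reporting/plotting."""
    import pandas as pd

    A = attractiveness(system, distance, kernel)
    return pd.DataFrame(
        {
            "unit_id": system.unit_id,
            "x": system.x,
            "A": A,
            "A_over_x": A / system.x,
        }
    )
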
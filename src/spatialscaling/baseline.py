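"""Conventional log-log straight-line fit of the scaling law.

Ordinary least squares of ln y on ln x, the textbook way of estimating the
exponent in y ~ x^beta.  Units with y = 0 must be excluded (their log is
undefined) — a known weakness of the approach; the number of excluded units
is reported.  The slope is base-invariant; the intercept is in natural log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .city_system import CitySystem


@dataclass(frozen=True)
class LinearFitResult:
    slope: float  # the scaling exponent beta of the straight-line fit
    intercept: float  # natural-log intercept
    n_used: int
    n_zero_dropped: int


def loglog_linear_fit(system: CitySystem) -> LinearFitResult:
    """OLS of ln y on ln x restricted to units with y > 0."""
    if system.y is None:
        raise ValueError("system has no observed counts")
    mask = system.y > 0
    n_used = int(mask.sum())
    if n_used < 2:
        raise ValueError("need at least 2 units with positive counts")
    res = linregress(np.log(system.x[mask]), np.log(system.y[mask]))
    return LinearFitResult(slope=float(res.slope), intercept=float(res.intercept),
                           n_used=n_used,
                           n_zero_dropped=system.n_units - n_used)
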
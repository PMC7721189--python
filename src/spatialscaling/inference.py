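"""MAP estimation of (alpha, beta), alpha-profiles and bootstrap uncertainty.

With flat priors the maximum-a-posteriori parameters are the likelihood
maximisers inside the prior support (beta in [0, 2], alpha in [0, alpha_max]).
At fixed alpha the log-likelihood is concave in beta — it is a linear
function of beta minus Y times a log-sum-exp of linear functions — so a
bracketed scalar search finds the unique maximiser.  The alpha search scans a
log-spaced grid (distances from sub-km to the Earth radius are all
admissible, but meaningful interaction scales are tens of km) and refines the
best grid point by a bracketed search in log-alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .city_system import CitySystem, DistanceMatrix
from .interaction import Kernel, attractiveness
from .likelihood import (
    ALPHA_MAX,
    BETA_BOUNDS,
    allocation_log_likelihood,
    log_multinomial_coefficient,
    token_probabilities,
)

#: spread (in log-likelihood units) below which the beta-profile is treated as flat
_FLAT_TOL = 1e-9


@dataclass(frozen=True)
class BetaFit:
    """Result of the 1-D beta maximisation at fixed attractiveness."""

    beta: float
    loglik: float  # full multinomial log-likelihood at the optimum
    boundary: bool = False  # maximiser on the edge of the prior support
    unidentified: bool = False  # likelihood flat in beta (e.g. huge alpha)


@dataclass
class ModelFit:
    """MAP fit of one model family.

    ``alpha`` is ``None`` for families without a spatial scale (P, C) and
    ``beta`` is fixed at 1 for the per-capita family.
    """

    family: str
    alpha: Optional[float]
    beta: float
    loglik: float
    beta_boundary: bool = False
    beta_unidentified: bool = False
    sigma_beta: Optional[float] = None
    profile: Optional[pd.DataFrame] = None


def fit_beta(x, y, A, beta_bounds=BETA_BOUNDS, tol: float = 1e-4) -> BetaFit:
    """Maximise the multinomial log-likelihood over beta at fixed A.

    The objective is concave, so a bounded Brent search suffices.  Boundary
    maxima are snapped to the support edge and flagged; a flat profile
    (unidentifiable beta, e.g. attractiveness constant across units) returns
    beta = 1 with the ``unidentified`` flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.asarray(A, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("beta is unidentifiable with fewer than 2 units")
    lo, hi = beta_bounds
    coeff = log_multinomial_coefficient(y)

    def alloc(b: float) -> float:
        return allocation_log_likelihood(y, x, A, b, beta_bounds)

    probes = [alloc(b) for b in np.linspace(lo, hi, 5)]
    if max(probes) - min(probes) < _FLAT_TOL:
        b0 = min(max(1.0, lo), hi)
        return BetaFit(beta=b0, loglik=coeff + alloc(b0), unidentified=True)

    res = minimize_scalar(
        lambda b: -alloc(b), bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    beta_hat, best = float(res.x), float(-res.fun)
    boundary = False
    # concavity: if an endpoint beats the interior optimum, the maximum is there
    for edge in (lo, hi):
        v = alloc(edge)
        if v >= best:
            beta_hat, best, boundary = edge, v, True
    if not boundary and min(beta_hat - lo, hi - beta_hat) < 2 * tol:
        edge = lo if beta_hat - lo < hi - beta_hat else hi
        v = alloc(edge)
        if v >= best - 1e-9:
            beta_hat, best, boundary = edge, v, True
    return BetaFit(beta=beta_hat, loglik=coeff + best, boundary=boundary)


def default_alpha_grid(alpha_max: float = ALPHA_MAX, n: int = 60,
                       alpha_min: float = 0.1) -> np.ndarray:
    """{0} plus ``n`` log-spaced points in [alpha_min, alpha_max] km."""
    return np.concatenate(([0.0], np.geomspace(alpha_min, alpha_max, n)))


def _attractiveness_at(system: CitySystem, distance: Optional[DistanceMatrix],
                       family: str, alpha: float) -> np.ndarray:
    if alpha == 0.0:
        return system.x.copy()
    return attractiveness(system, distance, Kernel(family, alpha))


def profile_alpha(system: CitySystem, distance: DistanceMatrix, family: str,
                  alpha_grid: Sequence[float], beta_bounds=BETA_BOUNDS,
                  beta_tol: float = 1e-4) -> pd.DataFrame:
    """beta-hat and max log-likelihood along a grid of alpha values.

    For each alpha the attractiveness vector is computed once and the
    concave beta maximisation is run on it.  Returns a tidy frame with
    columns ``alpha_km``, ``beta_hat``, ``loglik``, ``beta_boundary``,
    ``beta_unidentified``.
    """
    family = str(family).upper()
    if family not in ("G", "E"):
        raise ValueError("alpha profiles apply to the G and E families only")
    grid = np.asarray(list(alpha_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("alpha grid must not be empty")
    rows = []
    for alpha in grid:
        A = _attractiveness_at(system, distance, family, float(alpha))
        bf = fit_beta(system.x, system.y, A, beta_bounds, tol=beta_tol)
        rows.append(
            {
                "alpha_km": float(alpha),
                "beta_hat": bf.beta,
                "loglik": bf.loglik,
                "beta_boundary": bf.boundary,
                "beta_unidentified": bf.unidentified,
            }
        )
    return pd.DataFrame(rows)


def map_fit(system: CitySystem, distance: Optional[DistanceMatrix], family: str,
            alpha_grid: Optional[Sequence[float]] = None,
            beta_bounds=BETA_BOUNDS, beta_tol: float = 1e-4,
            alpha_rel_tol: float = 0.01, alpha_max: float = ALPHA_MAX,
            keep_profile: bool = True) -> ModelFit:
    """Joint MAP fit of one family.

    P: no free parameters (beta = 1).  C: 1-D beta fit with A = x.
    G/E: coarse log-spaced alpha scan refined by a bracketed search in
    log-alpha around the best grid point (relative tolerance
    ``alpha_rel_tol``), each evaluation re-fitting beta.
    """
    family = str(family).upper()
    if family not in ("P", "C", "G", "E"):
        raise ValueError(f"unknown model family {family!r}")
    if system.n_units < 2:
        raise ValueError("model fitting needs at least 2 units")
    x, y = system.x, system.y
    if y is None:
        raise ValueError("system has no observed counts to fit")

    if family == "P":
        from .likelihood import log_likelihood

        return ModelFit(family="P", alpha=None, beta=1.0,
                        loglik=log_likelihood(y, x, x, 1.0))

    if family == "C":
        bf = fit_beta(x, y, x, beta_bounds, tol=beta_tol)
        return ModelFit(family="C", alpha=None, beta=bf.beta, loglik=bf.loglik,
                        beta_boundary=bf.boundary,
                        beta_unidentified=bf.unidentified)

    if distance is None:
        distance = DistanceMatrix.from_system(system)
    grid = (np.asarray(list(alpha_grid), dtype=float) if alpha_grid is not None
            else default_alpha_grid(alpha_max))
    prof = profile_alpha(system, distance, family, grid, beta_bounds, beta_tol)
    i = int(prof["loglik"].idxmax())
    best_alpha = float(prof.loc[i, "alpha_km"])

    def eval_alpha(alpha: float) -> BetaFit:
        A = _attractiveness_at(system, distance, family, alpha)
        return fit_beta(x, y, A, beta_bounds, tol=beta_tol)

    cand = [(float(prof.loc[i, "loglik"]), best_alpha,
             bool(prof.loc[i, "beta_boundary"]),
             bool(prof.loc[i, "beta_unidentified"]),
             float(prof.loc[i, "beta_hat"]))]
    if best_alpha > 0.0:
        # refine in log-alpha between the neighbouring grid points
        left = float(grid[i - 1]) if i > 0 and grid[i - 1] > 0 else best_alpha / 100.0
        right = float(grid[i + 1]) if i < len(grid) - 1 else best_alpha
        if right > left:
            res = minimize_scalar(
                lambda t: -eval_alpha(float(np.exp(t))).loglik,
                bounds=(np.log(left), np.log(right)), method="bounded",
                options={"xatol": np.log1p(alpha_rel_tol)},
            )
            a_ref = float(np.exp(res.x))
            bf = eval_alpha(a_ref)
            cand.append((bf.loglik, a_ref, bf.boundary, bf.unidentified, bf.beta))
    loglik, alpha_hat, bdry, unid, beta_hat = max(cand, key=lambda c: c[0])
    return ModelFit(family=family, alpha=alpha_hat, beta=beta_hat, loglik=loglik,
                    beta_boundary=bdry, beta_unidentified=unid,
                    profile=prof if keep_profile else None)


def bootstrap_sigma_beta(system: CitySystem, distance: Optional[DistanceMatrix],
                         fit: ModelFit, n_boot: int = 100,
                         seed: Optional[int] = None,
                         beta_bounds=BETA_BOUNDS, beta_tol: float = 1e-4) -> float:
    """Parametric-bootstrap standard error of beta-hat.

    Draws ``n_boot`` replicate count vectors y* ~ Multinomial(Y, p-hat) at
    the MAP, re-fits beta on each (alpha held at its MAP value), and returns
    the sample standard deviation of the replicate estimates.  Deterministic
    given ``seed``.
    """
    if fit.family == "P":
        raise ValueError("the per-capita family has no fitted exponent")
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    x = system.x
    if fit.family == "C" or not fit.alpha:
        A = x.copy()
    else:
        A = attractiveness(system, distance, Kernel(fit.family, fit.alpha))
    p = token_probabilities(x, A, fit.beta, beta_bounds)
    total = system.total_tokens
    n_tokens = int(round(total))
    if abs(total - n_tokens) > 1e-9:
        warnings.warn(
            f"total count Y={total} is not an integer; rounding to {n_tokens} "
            "for multinomial resampling", UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_tokens, p, size=n_boot)
    betas = [fit_beta(x, ystar, A, beta_bounds, tol=beta_tol).beta for ystar in draws]
    return float(np.std(betas, ddof=1))
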
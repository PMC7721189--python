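"""Model/Results interface over the token-allocation framework.

``ScalingLawModel`` holds the data (a :class:`CitySystem`, its distances and
a model family) and ``fit()`` returns a ``ScalingLawResults`` carrying the
MAP estimates, their bootstrap uncertainty, diagnostics, and a ``summary()``
table; simulation of replicate datasets hangs off the results object.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .city_system import CitySystem, DistanceMatrix
from .interaction import Kernel, attractiveness, attractiveness_ratio
from .likelihood import (
    ALPHA_MAX,
    BETA_BOUNDS,
    expected_tokens,
    log_likelihood,
    token_probabilities,
)
from .inference import ModelFit, bootstrap_sigma_beta, map_fit, profile_alpha
from .selection import PriorSpec, description_length, log_evidence


class ScalingLawModel:
    """Multinomial token-allocation model of an urban scaling law.

    Parameters
    ----------
    system
        Spatial units with populations and observed counts.
    distance
        Pairwise distances in km; built from the unit centroids (haversine)
        when omitted and the family needs one.
    family
        "P" (per-capita), "C" (city), "G" (gravitational) or "E"
        (exponential).
    alpha_max, beta_bounds
        Prior support of the kernel scale and the scaling exponent.
    """

    def __init__(self, system: CitySystem,
                 distance: Optional[DistanceMatrix] = None, family: str = "G",
                 alpha_max: float = ALPHA_MAX, beta_bounds=BETA_BOUNDS):
        family = str(family).upper()
        if family not in ("P", "C", "G", "E"):
            raise ValueError(f"unknown model family {family!r}")
        if distance is None and family in ("G", "E"):
            distance = DistanceMatrix.from_system(system)
        self.system = system
        self.distance = distance
        self.family = family
        self.alpha_max = float(alpha_max)
        self.beta_bounds = tuple(beta_bounds)
        self._A_cache: Dict[float, np.ndarray] = {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, family: str = "G",
                       distance: Optional[DistanceMatrix] = None, **kwargs
                       ) -> "ScalingLawModel":
        return cls(CitySystem.from_dataframe(df), distance=distance,
                   family=family, **kwargs)

    # -- building blocks ---------------------------------------------------

    def attractiveness(self, alpha: Optional[float] = None) -> np.ndarray:
        """A_i at the given kernel scale, computed once per alpha and cached."""
        if self.family in ("P", "C") or not alpha:
            return self.system.x.copy()
        alpha = float(alpha)
        if alpha not in self._A_cache:
            self._A_cache[alpha] = attractiveness(
                self.system, self.distance, Kernel(self.family, alpha))
        return self._A_cache[alpha]

    def loglike(self, beta: float = 1.0, alpha: Optional[float] = None) -> float:
        """Full multinomial log-likelihood at (alpha, beta)."""
        A = self.attractiveness(alpha)
        return log_likelihood(self.system.y, self.system.x, A, beta,
                              self.beta_bounds)

    # -- estimation --------------------------------------------------------

    def fit(self, alpha_grid: Optional[Sequence[float]] = None,
            beta_tol: float = 1e-4, alpha_rel_tol: float = 0.01,
            keep_profile: bool = True) -> "ScalingLawResults":
        """MAP fit; returns a results object."""
        mf = map_fit(self.system, self.distance, self.family,
                     alpha_grid=alpha_grid, beta_bounds=self.beta_bounds,
                     beta_tol=beta_tol, alpha_rel_tol=alpha_rel_tol,
                     alpha_max=self.alpha_max, keep_profile=keep_profile)
        return ScalingLawResults(self, mf)

    def profile(self, alpha_grid: Sequence[float]) -> pd.DataFrame:
        """beta-hat and max log-likelihood along an alpha grid (G/E only)."""
        return profile_alpha(self.system, self.distance, self.family,
                             alpha_grid, self.beta_bounds)


class ScalingLawResults:
    """MAP estimates, uncertainty and diagnostics of a fitted model."""

    def __init__(self, model: ScalingLawModel, fit: ModelFit):
        self.model = model
        self._fit = fit

    # -- estimates ---------------------------------------------------------

    @property
    def family(self) -> str:
        return self._fit.family

    @property
    def alpha(self) -> Optional[float]:
        """MAP kernel scale in km (None for P and C)."""
        return self._fit.alpha

    @property
    def beta(self) -> float:
        """MAP scaling exponent (fixed at 1 for P)."""
        return self._fit.beta

    @property
    def llf(self) -> float:
        """Maximised log-likelihood."""
        return self._fit.loglik

    @property
    def beta_boundary(self) -> bool:
        return self._fit.beta_boundary

    @property
    def beta_unidentified(self) -> bool:
        return self._fit.beta_unidentified

    @property
    def sigma_beta(self) -> Optional[float]:
        return self._fit.sigma_beta

    @property
    def profile(self) -> Optional[pd.DataFrame]:
        return self._fit.profile

    # -- uncertainty and diagnostics ---------------------------------------

    def bootstrap_sigma_beta(self, n_boot: int = 100,
                             seed: Optional[int] = None) -> float:
        """Parametric-bootstrap standard error of beta-hat (cached)."""
        s = bootstrap_sigma_beta(self.model.system, self.model.distance,
                                 self._fit, n_boot=n_boot, seed=seed,
                                 beta_bounds=self.model.beta_bounds)
        self._fit.sigma_beta = s
        return s

    def token_probabilities(self) -> np.ndarray:
        A = self.model.attractiveness(self.alpha)
        return token_probabilities(self.model.system.x, A, self.beta,
                                   self.model.beta_bounds)

    def expected_counts(self) -> pd.DataFrame:
        """Observed vs model-expected counts per unit."""
        sys_ = self.model.system
        return pd.DataFrame(
            {
                "unit_id": sys_.unit_id,
                "population": sys_.x,
                "count_observed": sys_.y,
                "count_expected": expected_tokens(sys_.total_tokens,
                                                  self.token_probabilities()),
            }
        )

    def attractiveness_ratio(self) -> np.ndarray:
        """A_i / x_i at the fitted kernel scale (all ones for P and C)."""
        if self.family in ("P", "C") or not self.alpha:
            return np.ones(self.model.system.n_units)
        return attractiveness_ratio(self.model.system, self.model.distance,
                                    Kernel(self.family, self.alpha))

    def description_length(self, priors: Optional[PriorSpec] = None,
                           tol_bytes: float = 0.1) -> float:
        """Description length (bytes) of this family on the data."""
        ev = log_evidence(self.model.system, self.model.distance, self.family,
                          priors=priors, tol_bytes=tol_bytes, fit=self._fit)
        return ev.dl_bytes

    def simulate(self, seed: Optional[int] = None, size: int = 1) -> np.ndarray:
        """Replicate count vectors drawn from the fitted multinomial."""
        rng = np.random.default_rng(seed)
        p = self.token_probabilities()
        n_tokens = int(round(self.model.system.total_tokens))
        return rng.multinomial(n_tokens, p, size=size).astype(float)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        sys_ = self.model.system
        lines = [
            "Token-allocation scaling-law model",
            "=" * 42,
            f"family:            {self.family}",
            f"n units:           {sys_.n_units}",
            f"total population:  {sys_.total_population:.6g}",
            f"total tokens Y:    {sys_.total_tokens:.6g}",
        ]
        if self.alpha is not None:
            lines.append(f"alpha (km):        {self.alpha:.6g}")
        if self.family == "P":
            lines.append("beta:              1 (fixed)")
        else:
            flag = ""
            if self.beta_boundary:
                flag = "  [boundary]"
            if self.beta_unidentified:
                flag = "  [unidentified]"
            lines.append(f"beta:              {self.beta:.4f}{flag}")
        if self.sigma_beta is not None:
            lines.append(f"sigma_beta (boot): {self.sigma_beta:.4f}")
        lines.append(f"log-likelihood:    {self.llf:.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        a = f", alpha={self.alpha:.3g}" if self.alpha is not None else ""
        return (f"<ScalingLawResults family={self.family}{a} "
                f"beta={self.beta:.4f}>")
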
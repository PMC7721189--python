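"""Multinomial token-allocation likelihood.

Given populations x_i and attractiveness A_i, a token lands in unit i with
probability

    p_i = x_i A_i^(beta-1) / Z(beta),    Z(beta) = sum_i x_i A_i^(beta-1),

and the Y observed tokens are one multinomial draw:

    ln P(y | x, A, beta) = ln Y! - sum_i ln y_i!
                           + sum_i y_i ln p_i.

All probability work is done in log space with log-sum-exp: populations and
attractiveness span many orders of magnitude and beta-1 powers overflow naive
arithmetic.  Non-integer counts (GDP, road miles) are accepted; the
multinomial coefficient uses the log-gamma continuous extension, which is
model-independent and cancels in every model comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

#: prior support of the scaling exponent beta
BETA_BOUNDS = (0.0, 2.0)
#: prior support ceiling of the kernel scale alpha, km (Earth's radius)
ALPHA_MAX = 6371.0


def _check_beta(beta: float, beta_bounds=BETA_BOUNDS) -> None:
    lo, hi = beta_bounds
    if not (lo <= beta <= hi):
        raise ValueError(f"beta={beta} outside prior support [{lo}, {hi}]")


def log_token_probabilities(x, A, beta: float, beta_bounds=BETA_BOUNDS) -> np.ndarray:
    """log p_i = ln x_i + (beta-1) ln A_i - ln Z(beta), computed stably."""
    _check_beta(beta, beta_bounds)
    x = np.asarray(x, dtype=float)
    A = np.asarray(A, dtype=float)
    scores = np.log(x) + (beta - 1.0) * np.log(A)
    return scores - logsumexp(scores)


def token_probabilities(x, A, beta: float, beta_bounds=BETA_BOUNDS) -> np.ndarray:
    """Allocation probabilities p_i; sums to 1."""
    return np.exp(log_token_probabilities(x, A, beta, beta_bounds))


def log_normalization(x, A, beta: float) -> float:
    """ln Z(beta) = ln sum_i x_i A_i^(beta-1)."""
    x = np.asarray(x, dtype=float)
    A = np.asarray(A, dtype=float)
    return float(logsumexp(np.log(x) + (beta - 1.0) * np.log(A)))


def expected_tokens(total_tokens: float, p) -> np.ndarray:
    """Expected counts Y * p_i; sums to Y."""
    return float(total_tokens) * np.asarray(p, dtype=float)


def log_multinomial_coefficient(y) -> float:
    """ln Y! - sum_i ln y_i!, via log-gamma (valid for non-integer y)."""
    y = np.asarray(y, dtype=float)
    return float(gammaln(y.sum() + 1.0) - gammaln(y + 1.0).sum())


def allocation_log_likelihood(y, x, A, beta: float, beta_bounds=BETA_BOUNDS) -> float:
    """The model-dependent term sum_i y_i ln p_i.

    This is the only part of the log-likelihood that varies across model
    families and parameters; the multinomial coefficient is shared.
    Units with y_i = 0 contribute zero (p_i > 0 always since x_i > 0).
    """
    y = np.asarray(y, dtype=float)
    return float(y @ log_token_probabilities(x, A, beta, beta_bounds))


def allocation_log_likelihood_grid(y, x, A, betas, beta_bounds=BETA_BOUNDS) -> np.ndarray:
    """Vectorised ``allocation_log_likelihood`` over a grid of beta values."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    A = np.asarray(A, dtype=float)
    b = np.atleast_1d(np.asarray(betas, dtype=float))
    lo, hi = beta_bounds
    if np.any(b < lo) or np.any(b > hi):
        raise ValueError(f"beta grid extends outside prior support [{lo}, {hi}]")
    lnx = np.log(x)
    lnA = np.log(A)
    scores = lnx[None, :] + (b[:, None] - 1.0) * lnA[None, :]
    logZ = logsumexp(scores, axis=1)
    return scores @ y - y.sum() * logZ


def log_likelihood(y, x, A, beta: float, beta_bounds=BETA_BOUNDS) -> float:
    """Full multinomial log-likelihood ln P(y | x, A, beta)."""
    return log_multinomial_coefficient(y) + allocation_log_likelihood(
        y, x, A, beta, beta_bounds
    )
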
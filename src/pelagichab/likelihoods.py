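"""Count likelihoods (log link): Poisson and mean/size negative binomial.

The negative binomial is parameterized by mean mu and size k, with
variance mu + mu^2 / k; as k -> infinity it degenerates to the Poisson.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["count_loglik", "grad_hess_eta"]


def count_loglik(y, mu, family: str, size: float | None = None) -> np.ndarray:
    """Per-observation log-likelihood; vectorized and finite for large counts."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu must be positive and finite")
    if family == "poisson":
        return y * np.log(mu) - mu - gammaln(y + 1)
    if family == "negative_binomial":
        if size is None or not size > 0:
            raise ValueError("negative binomial needs size > 0")
        return (
            gammaln(y + size) - gammaln(size) - gammaln(y + 1)
            + size * np.log(size / (size + mu))
            + y * np.log(mu / (size + mu))
        )
    raise ValueError(f"unknown family {family!r}")


def grad_hess_eta(y, eta, log_offset, family: str, size: float | None = None):
    """Gradient and (expected, Fisher) negative curvature of the log-likelihood
    with respect to the linear predictor eta, where mu = exp(log_offset + eta).

    Poisson:   d l/d eta = y - mu,            -d2 l = mu
    NB(size):  d l/d eta = (y - mu) k/(k+mu), -d2 l = mu k/(k + mu)
    """
    eta = np.clip(np.asarray(eta, dtype=float), -30.0, 30.0)
    mu = np.exp(log_offset + eta)
    if family == "poisson":
        g = y - mu
        w = mu
    elif family == "negative_binomial":
        k = float(size)
        g = (y - mu) * k / (k + mu)
        w = mu * k / (k + mu)
    else:
        raise ValueError(f"unknown family {family!r}")
    return g, np.maximum(w, 1e-10)
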
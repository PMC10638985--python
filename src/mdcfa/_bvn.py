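"""Standard bivariate normal rectangle probabilities.

Deterministic evaluation of the bivariate normal CDF through Owen's T
function, accurate to ~1e-14 and fully vectorized.  Used by the
tetrachoric solver, where cell probabilities of a 2x2 table are linear
combinations of Phi2 evaluated at the two latent thresholds.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "bvn_upper", "bvn_density"]

_TWO_PI = 2.0 * np.pi


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Owen (1956): Phi2(h, k; rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k)
    - beta, with beta = 1/2 when h*k < 0 (or h*k = 0 with h + k < 0).
    Inputs broadcast; |rho| must be < 1.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    # nudge exact zeros so the a_h = (k - rho h)/(h sqrt(1-rho^2)) limit is taken
    h = np.where(h == 0.0, 1e-15, h)
    k = np.where(k == 0.0, 1e-15, k)
    denom = np.sqrt(np.clip(1.0 - rho * rho, 1e-300, None))
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    beta = np.where(h * k < 0.0, 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - beta
    return np.clip(out, 0.0, 1.0)


def bvn_upper(h, k, rho):
    """P(X > h, Y > k) — the survival-quadrant probability."""
    return bvn_cdf(-np.asarray(h, dtype=float), -np.asarray(k, dtype=float), rho)


def bvn_density(h, k, rho):
    """Standard bivariate normal density at (h, k)."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    om = 1.0 - rho * rho
    z = (h * h - 2.0 * rho * h * k + k * k) / om
    return np.exp(-0.5 * z) / (_TWO_PI * np.sqrt(om))
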
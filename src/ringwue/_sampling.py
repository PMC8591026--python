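"""Low-level random-variate helpers shared by the Gibbs samplers."""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri


def truncated_normal(mean: float, sd: float, lo: float, hi: float,
                     rng: np.random.Generator) -> float:
    """One draw from N(mean, sd^2) truncated to [lo, hi].

    Inverse-CDF sampling; exact and cheap for the wide bounds used by the
    hyper-mean full conditionals.
    """
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    if b - a < 1e-300:
        # conditional mass is numerically outside [lo, hi]; clamp
        return lo if mean < lo else hi
    u = rng.uniform(a, b)
    return mean + sd * ndtri(u)


def inverse_gamma(shape: float, rate: float, rng: np.random.Generator) -> float:
    """One draw from an inverse-gamma with the shape/rate convention
    (density proportional to x**(-shape-1) * exp(-rate/x))."""
    return rate / rng.gamma(shape)


def mvn_from_precision(b: np.ndarray, prec: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw from N(prec^-1 b, prec^-1) given the canonical parameters.

    Uses the Cholesky factor of the precision matrix: solve for the mean,
    then add back-substituted standard normals.
    """
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, b)
    z = rng.standard_normal(b.shape[0])
    return mean + np.linalg.solve(chol.T, z)
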
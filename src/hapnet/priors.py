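"""Penalised-complexity (PC) priors.

PC priors place an exponential density on the distance d(x) from a simple
base model, calibrated through a tail statement P(x > u) = alpha.  Two kinds
are used here: a prior on a standard deviation (base model: the effect is
absent, d(sigma) = sigma) and a prior on the AR(1) autocorrelation with base
model rho = 1 (haplotypes one mutation apart have identical effects), for
which d(rho) = sqrt(1 - rho).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

__all__ = ["PCPriorSpec", "pc_prior_sd", "pc_prior_ar1_base1"]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class PCPriorSpec:
    """A calibrated PC prior: proper density with P(x > u) = alpha."""

    kind: str                      # "sd" or "ar1_base1"
    u: float
    alpha: float
    rate: float                    # exponential rate on the distance scale
    support: tuple[float, float]
    log_density: Callable[[np.ndarray], np.ndarray]

    def density(self, x) -> np.ndarray:
        return np.exp(self.log_density(x))


def pc_prior_sd(u: float, alpha: float) -> PCPriorSpec:
    """PC prior for a standard deviation: sigma ~ Exp(lambda), P(sigma>u)=alpha.

    The base model sets the component's variance to zero; the distance from
    it is the standard deviation itself, so the prior is exponential with
    rate lambda = -ln(alpha)/u.
    """
    if not u > 0:
        raise ValueError(f"u must be > 0, got {u}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lam = -math.log(alpha) / u

    def log_density(sigma):
        sigma = np.asarray(sigma, dtype=float)
        out = np.where(sigma >= 0, math.log(lam) - lam * sigma, -np.inf)
        return out if out.ndim else float(out)

    return PCPriorSpec("sd", u, alpha, lam, (0.0, math.inf), log_density)


def _ar1_tail(theta: float, u: float) -> float:
    """P(rho > u) under rate theta: exponential on d = sqrt(1-rho), d < sqrt2."""
    a = math.sqrt(1.0 - u)
    return -math.expm1(-theta * a) / -math.expm1(-theta * _SQRT2)


def pc_prior_ar1_base1(u_rho: float, alpha_rho: float) -> PCPriorSpec:
    """PC prior for the AR(1) autocorrelation with base model rho = 1.

    The complexity distance is d(rho) = sqrt(1 - rho); an exponential density
    with rate theta is placed on d, truncated to d in (0, sqrt(2)) (i.e.
    rho in (-1, 1)) and transformed back to rho with its Jacobian.  theta is
    calibrated numerically so that P(rho > u_rho) = alpha_rho.

    Raises ValueError when (u, alpha) violate the admissibility constraint
    alpha > (1 - u)/2, and ArithmeticError when calibration has no root
    (the truncated-exponential family cannot reach tail probabilities below
    sqrt((1 - u)/2), its theta -> 0 limit).
    """
    if not -1 < u_rho < 1:
        raise ValueError(f"u_rho must be in (-1, 1), got {u_rho}")
    if not (1.0 - u_rho) / 2.0 < alpha_rho < 1:
        raise ValueError(
            f"alpha_rho must satisfy (1-u_rho)/2 < alpha_rho < 1; "
            f"got u_rho={u_rho}, alpha_rho={alpha_rho}"
        )

    def f(theta: float) -> float:
        return _ar1_tail(theta, u_rho) - alpha_rho

    lo, hi = 1e-9, 1.0
    while f(hi) < 0 and hi < 1e6:
        hi *= 2.0
    if f(lo) * f(hi) > 0:
        raise ArithmeticError(
            f"PC-prior calibration failed: no rate theta gives "
            f"P(rho > {u_rho}) = {alpha_rho}"
        )
    theta = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    log_norm = math.log(-math.expm1(-theta * _SQRT2))

    def log_density(rho):
        rho = np.asarray(rho, dtype=float)
        inside = (rho > -1) & (rho < 1)
        d = np.sqrt(np.clip(1.0 - rho, 1e-300, None))
        # |dd/drho| = 1/(2 d)
        ld = math.log(theta) - theta * d - np.log(2.0 * d) - log_norm
        out = np.where(inside, ld, -np.inf)
        return out if out.ndim else float(out)

    return PCPriorSpec(
        "ar1_base1", u_rho, alpha_rho, theta, (-1.0, 1.0), log_density
    )
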
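"""Model scoring: Gaussian CRPS, RCRPS, RMSE, strata, variance proportions.

The continuous ranked probability score (CRPS) of a predictive distribution F
against a realised value y is the integral of (F(x) - 1{x >= y})^2.  Posterior
marginals here are mixtures of Gaussians that are close to Gaussian, so each
is scored with the closed-form Gaussian CRPS of its mixture mean and variance.
The relative CRPS (RCRPS) between two models over the same haplotype set is
the log of the ratio of their summed CRPS: negative values favour the first
model.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

__all__ = [
    "crps_gaussian",
    "crps_gaussian_mixture",
    "rcrps",
    "rmse",
    "stratify_by_observation",
    "variance_proportions",
]

_INV_SQRT_PI = 1.0 / math.sqrt(math.pi)


def crps_gaussian(mu, sigma, truth):
    """Closed-form CRPS of a Gaussian N(mu, sigma^2) forecast against truth.

    CRPS = sigma * [z (2 Phi(z) - 1) + 2 phi(z) - 1/sqrt(pi)], with
    z = (truth - mu) / sigma; a point forecast (sigma = 0) scores |truth - mu|.
    Broadcasts over arrays.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if (sigma < 0).any():
        raise ValueError("sigma must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (truth - mu) / np.where(sigma > 0, sigma, 1.0),
                     0.0)
        out = sigma * (z * (2.0 * norm.cdf(z) - 1.0) + 2.0 * norm.pdf(z)
                       - _INV_SQRT_PI)
    out = np.where(sigma == 0, np.abs(truth - mu), out)
    return float(out) if out.ndim == 0 else out


def crps_gaussian_mixture(means, sds, weights, truth) -> float:
    """Exact CRPS of a Gaussian mixture (sensitivity-check alternative).

    Uses the closed form for mixtures: E|X - y| - 0.5 E|X - X'| with
    E|N(m, s^2)| = m (2 Phi(m/s) - 1) + 2 s phi(m/s).
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    w = np.asarray(weights, float)
    w = w / w.sum()

    def e_abs(m, s):
        s = np.where(s > 0, s, 1e-300)
        return m * (2.0 * norm.cdf(m / s) - 1.0) + 2.0 * s * norm.pdf(m / s)

    term1 = float(np.sum(w * e_abs(means - truth, sds)))
    dm = means[:, None] - means[None, :]
    ds = np.sqrt(sds[:, None] ** 2 + sds[None, :] ** 2)
    term2 = float(w @ e_abs(dm, ds) @ w)
    return term1 - 0.5 * term2


def rcrps(crps_model, crps_reference) -> float:
    """log of the ratio of summed CRPS (model over reference); < 0 favours
    the model."""
    a = np.asarray(crps_model, dtype=float)
    b = np.asarray(crps_reference, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValueError("CRPS vectors must have equal positive length")
    sb = float(b.sum())
    if sb <= 0:
        raise ValueError("reference CRPS sum must be > 0")
    return math.log(float(a.sum()) / sb)


def rmse(estimates, truths) -> float:
    a = np.asarray(estimates, dtype=float)
    b = np.asarray(truths, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValueError("vectors must have equal positive length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def stratify_by_observation(Z, is_phantom=None) -> np.ndarray:
    """Label each haplotype by phenotype-observation count.

    ``never`` (0 carriers), ``once`` (1), ``several`` (>= 2); phantom
    haplotypes are always ``never``.
    """
    Z = np.asarray(Z)
    counts = Z.sum(axis=0)
    labels = np.where(counts == 0, "never",
                      np.where(counts == 1, "once", "several"))
    if is_phantom is not None:
        labels = np.where(np.asarray(is_phantom, bool), "never", labels)
    return labels.astype(object)


def variance_proportions(components: dict[str, float]) -> dict[str, float]:
    """Share of the total model variance per named component.

    For the haplotype-network term the marginal variance sigma2_hm (not the
    conditional one) enters the total.
    """
    if len(components) < 2:
        raise ValueError("need at least two variance components")
    vals = np.array(list(components.values()), dtype=float)
    if (vals < 0).any():
        raise ValueError("variance components must be >= 0")
    total = vals.sum()
    if total == 0:
        raise ValueError("all variance components are zero")
    return {k: float(v / total) for k, v in zip(components, vals)}
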
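"""Bayesian phenotype model with haplotype effects.

The observation model is

    y = X beta + f_1 + ... + f_s + Z h + e,

with a Gaussian likelihood on centred/scaled phenotypes, vague Gaussian fixed
effects beta ~ N(0, I * 1000), optional extra random effects f (i.i.d. or
with a user-supplied covariance), a haplotype term and residuals
e ~ N(0, I sigma2_e).  Three haplotype terms are supported:

* ``hn``        -- the haplotype-network model, h ~ N(0, V_h(rho, sigma2_hc))
                   with the sparse AR(1)-on-a-DAG precision;
* ``ih``        -- independent haplotype effects, h ~ N(0, I sigma2_I);
* ``mutation``  -- h = U v with per-site effects v ~ N(0, I sigma2_v).

Because the likelihood is Gaussian the latent field can be integrated out
exactly for fixed hyper-parameters; the few hyper-parameters (variances, and
rho for the HN term) are handled by numerical integration on a grid centred
at the posterior mode, scaled by the numerical Hessian.  This mirrors the
structure of latent-Gaussian-model machinery, made exact by the Gaussian
likelihood.  There is no global intercept: the mean level of the phenotypes
is absorbed by the haplotype effects, since an intercept and the haplotype
level are not identifiable as rho approaches 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .graph import AlleleMatrix, HaplotypeDAG
from .precision import PrecisionComponents, precision_components
from .priors import PCPriorSpec, pc_prior_ar1_base1, pc_prior_sd

__all__ = [
    "RandomTerm",
    "ModelPriors",
    "GridSettings",
    "HaplotypeModel",
    "HaplotypeResults",
    "InferenceError",
    "assemble_model",
    "log_marginal_likelihood",
    "fit",
    "estimate_mutation_effects",
    "derive_conditional_variance_posterior",
]

_LOG2PI = math.log(2.0 * math.pi)


class InferenceError(RuntimeError):
    """Numerical failure during posterior computation."""


@dataclass
class RandomTerm:
    """An extra random effect f ~ N(0, C sigma2) with design matrix ``design``.

    ``structure`` is ``"iid"`` (C = I) or ``"user_covariance"`` (C supplied
    via ``covariance`` or its inverse via ``precision``, e.g. a pedigree
    relationship matrix).
    """

    name: str
    design: np.ndarray
    structure: str = "iid"
    covariance: Optional[np.ndarray] = None
    precision: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError(f"term {self.name!r}: design must be 2-d")
        if self.structure not in ("iid", "user_covariance"):
            raise ValueError(f"term {self.name!r}: unknown structure "
                             f"{self.structure!r}")
        if self.structure == "user_covariance":
            if self.covariance is None and self.precision is None:
                raise ValueError(f"term {self.name!r}: user_covariance needs a "
                                 "covariance or precision matrix")
            if self.precision is None:
                self.precision = np.linalg.inv(np.asarray(self.covariance, float))
            self.precision = np.asarray(self.precision, dtype=float)
            q = self.design.shape[1]
            if self.precision.shape != (q, q):
                raise ValueError(f"term {self.name!r}: precision shape mismatch")


@dataclass
class ModelPriors:
    """Priors for the hyper-parameters.

    ``sd`` applies to every standard-deviation parameter unless overridden by
    name in ``sd_overrides`` (keys are hyper-parameter names such as
    ``"sigma2_hm"`` or ``"sigma2_e"``; the prior itself lives on the sd
    scale).  ``rho`` is the AR(1) autocorrelation prior with base model
    rho = 1.  Defaults are u = 0.1, alpha = 0.8 for all sds and u = 0.7,
    alpha = 0.8 for rho.
    """

    sd: PCPriorSpec = field(default_factory=lambda: pc_prior_sd(0.1, 0.8))
    rho: PCPriorSpec = field(default_factory=lambda: pc_prior_ar1_base1(0.7, 0.8))
    sd_overrides: dict[str, PCPriorSpec] = field(default_factory=dict)

    def sd_prior(self, hyper_name: str) -> PCPriorSpec:
        return self.sd_overrides.get(hyper_name, self.sd)


@dataclass
class GridSettings:
    """Hyper-parameter integration grid: mode +/- extent * sd per dimension."""

    points_per_dim: int = 7
    extent: float = 3.0
    prune_log_drop: float = 10.0
    max_opt_iter: int = 1500

    def __post_init__(self) -> None:
        if self.points_per_dim < 3 or self.points_per_dim % 2 == 0:
            raise ValueError("points_per_dim must be an odd integer >= 3")


def _rho_to_internal(rho: float) -> float:
    return math.log((1.0 + rho) / (1.0 - rho))


def _rho_from_internal(r: np.ndarray | float):
    return np.tanh(np.asarray(r) / 2.0)


class HaplotypeModel:
    """Phenotype model with a haplotype-effect term (HN / IH / mutation).

    Parameters
    ----------
    y
        Phenotype vector (length p), assumed centred and scaled.
    Z
        p x n_h incidence matrix over the *named* haplotypes: one 1 per row
        for haploid data, two for diploid.
    haplotype_ids
        Column labels of ``Z``.  Defaults to the non-phantom nodes of ``dag``
        in topological order (HN/IH) or the rows of ``allele_matrix``
        (mutation model).
    term
        ``"hn"`` (requires ``dag``), ``"ih"``, or ``"mutation"`` (requires
        ``allele_matrix``).
    X
        Optional p x r fixed-effect design.  A constant (intercept) column is
        rejected unless ``allow_intercept=True``.
    extra_terms
        Extra :class:`RandomTerm` effects.
    priors
        :class:`ModelPriors`; defaults to the PC priors above.
    rho_fixed
        Fix the HN autocorrelation instead of inferring it (rho_fixed = 0
        reproduces the IH model exactly).
    sum_to_zero
        Add a soft sum-to-zero constraint on the haplotype effects.
    """

    def __init__(
        self,
        y,
        Z,
        term: str = "hn",
        *,
        dag: Optional[HaplotypeDAG] = None,
        allele_matrix: Optional[AlleleMatrix] = None,
        haplotype_ids: Optional[Sequence[str]] = None,
        X=None,
        extra_terms: Sequence[RandomTerm] = (),
        priors: Optional[ModelPriors] = None,
        fixed_prior_var: float = 1000.0,
        rho_fixed: Optional[float] = None,
        allow_intercept: bool = False,
        sum_to_zero: bool = False,
    ) -> None:
        self.y = np.asarray(y, dtype=float).ravel()
        p = self.y.size
        self.term = term
        self.dag = dag
        self.allele_matrix = allele_matrix
        self.priors = priors if priors is not None else ModelPriors()
        self.fixed_prior_var = float(fixed_prior_var)
        self.rho_fixed = rho_fixed
        self.sum_to_zero = sum_to_zero
        self.extra_terms = list(extra_terms)

        if term not in ("hn", "ih", "mutation"):
            raise ValueError(f"unknown haplotype term {term!r}")
        if term == "hn" and dag is None:
            raise ValueError("term='hn' requires a dag")
        if term == "mutation" and allele_matrix is None:
            raise ValueError("term='mutation' requires an allele_matrix")

        Z = np.asarray(sp.csr_matrix(Z).toarray() if sp.issparse(Z) else Z,
                       dtype=float)
        if Z.ndim != 2 or Z.shape[0] != p:
            raise ValueError("Z must be p x n_haplotypes")
        rowsum = Z.sum(axis=1)
        if p and not np.isin(rowsum, (1.0, 2.0)).all():
            raise ValueError("Z row sums must be 1 (haploid) or 2 (diploid)")

        if haplotype_ids is None:
            if term == "mutation":
                haplotype_ids = list(allele_matrix.haplotype_ids)
            elif dag is not None:
                haplotype_ids = [n for n in dag.topo_order
                                 if not dag.is_phantom[n]]
            else:
                haplotype_ids = [f"h{i}" for i in range(Z.shape[1])]
        haplotype_ids = list(haplotype_ids)
        if len(haplotype_ids) != Z.shape[1]:
            raise ValueError("haplotype_ids length does not match Z columns")
        self.haplotype_ids = haplotype_ids
        self.Z = Z
        self.n_phenotypes_per_haplotype = Z.sum(axis=0)

        if X is None:
            X = np.zeros((p, 0))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != p:
            raise ValueError("X row count must equal len(y)")
        if p and X.shape[1]:
            const = np.all(X == X[0, :], axis=0) & (X[0, :] != 0)
            if const.any() and not allow_intercept:
                raise ValueError(
                    "X contains a constant (intercept-like) column; the model "
                    "has no common intercept for identifiability (pass "
                    "allow_intercept=True to override)"
                )
        self.X = X

        for t in self.extra_terms:
            if t.design.shape[0] != p:
                raise ValueError(f"term {t.name!r}: design row count != p")

        self._build_latent_layout()
        self._build_design()
        self._build_hyper_layout()

    # -- layout --------------------------------------------------------------

    def _build_latent_layout(self) -> None:
        names: list[str] = [f"beta:{j}" for j in range(self.X.shape[1])]
        is_phantom: list[bool] = [False] * self.X.shape[1]
        self.beta_slice = slice(0, self.X.shape[1])
        pos = self.X.shape[1]
        self.term_slices: dict[str, slice] = {}
        for t in self.extra_terms:
            q = t.design.shape[1]
            self.term_slices[t.name] = slice(pos, pos + q)
            names += [f"{t.name}:{j}" for j in range(q)]
            is_phantom += [False] * q
            pos += q

        if self.term == "hn":
            if not self.dag.all_edges_single_mutation():
                raise ValueError("DAG has multi-mutation edges; call "
                                 "insert_phantom_haplotypes first")
            self._comp: Optional[PrecisionComponents] = \
                precision_components(self.dag)
            hap_labels = self._comp.node_order
            hap_phantom = [self.dag.is_phantom[n] for n in hap_labels]
        elif self.term == "ih":
            self._comp = None
            hap_labels = list(self.haplotype_ids)
            hap_phantom = [False] * len(hap_labels)
        else:  # mutation: latent variables are per-site effects
            self._comp = None
            hap_labels = [f"v:{s}" for s in self.allele_matrix.site_ids]
            hap_phantom = [False] * len(hap_labels)

        self.hap_slice = slice(pos, pos + len(hap_labels))
        self.hap_labels = hap_labels
        names += list(hap_labels)
        is_phantom += hap_phantom
        self.latent_names = names
        self.latent_is_phantom = np.array(is_phantom, dtype=bool)
        self.n_latent = pos + len(hap_labels)

    def _build_design(self) -> None:
        p = self.y.size
        if self.term == "hn":
            # map named-haplotype incidence onto the full latent node order;
            # phantom columns stay zero
            node_pos = {n: j for j, n in enumerate(self.hap_labels)}
            Zh = np.zeros((p, len(self.hap_labels)))
            for col, hid in enumerate(self.haplotype_ids):
                if hid not in node_pos:
                    raise KeyError(f"haplotype {hid!r} not a DAG node")
                Zh[:, node_pos[hid]] = self.Z[:, col]
        elif self.term == "ih":
            Zh = self.Z
        else:
            U = self.allele_matrix.reindex(self.haplotype_ids).U.astype(float)
            Zh = self.Z @ U
        blocks = [self.X] + [t.design for t in self.extra_terms] + [Zh]
        self.W = np.hstack(blocks) if blocks else np.zeros((p, 0))
        self._WtW = self.W.T @ self.W
        self._Wty = self.W.T @ self.y
        self._yty = float(self.y @ self.y)

    def _build_hyper_layout(self) -> None:
        names: list[str] = []
        for t in self.extra_terms:
            names.append(f"sigma2_{t.name}")
        if self.term == "hn":
            if self.rho_fixed is None:
                names.append("rho")
            names.append("sigma2_hm")
        elif self.term == "ih":
            names.append("sigma2_I")
        else:
            names.append("sigma2_v")
        names.append("sigma2_e")
        self.hyper_names = names
        self.n_hyper = len(names)

    # -- densities -------------------------------------------------------

    def _theta_dict(self, theta) -> dict[str, float]:
        """Internal vector -> natural-scale hyper-parameters."""
        if isinstance(theta, dict):
            return dict(theta)
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.size != self.n_hyper:
            raise ValueError(f"theta must have {self.n_hyper} entries "
                             f"({self.hyper_names})")
        out: dict[str, float] = {}
        for name, val in zip(self.hyper_names, theta):
            # clamp the internal scale: variances outside e^[-40, 40] only
            # arise while the optimiser probes absurd regions
            val = float(np.clip(val, -40.0, 40.0))
            out[name] = float(_rho_from_internal(val)) if name == "rho" \
                else math.exp(val)
        return out

    def _theta_internal(self, params: dict[str, float]) -> np.ndarray:
        vals = []
        for name in self.hyper_names:
            v = params[name]
            vals.append(_rho_to_internal(v) if name == "rho" else math.log(v))
        return np.array(vals)

    def _prior_precision(self, params: dict[str, float]):
        """Dense latent prior precision and its log-determinant."""
        m = self.n_latent
        P = np.zeros((m, m))
        logdet = 0.0
        r = self.X.shape[1]
        if r:
            P[self.beta_slice, self.beta_slice] = \
                np.eye(r) / self.fixed_prior_var
            logdet += -r * math.log(self.fixed_prior_var)
        for t in self.extra_terms:
            s2 = params[f"sigma2_{t.name}"]
            sl = self.term_slices[t.name]
            q = sl.stop - sl.start
            if t.structure == "iid":
                P[sl, sl] = np.eye(q) / s2
                logdet += -q * math.log(s2)
            else:
                P[sl, sl] = t.precision / s2
                sign, ld0 = np.linalg.slogdet(t.precision)
                if sign <= 0:
                    raise InferenceError(f"term {t.name!r}: precision not PD")
                logdet += ld0 - q * math.log(s2)
        sl = self.hap_slice
        q = sl.stop - sl.start
        if self.term == "hn":
            rho = params["rho"] if self.rho_fixed is None else self.rho_fixed
            s2hm = params["sigma2_hm"]
            s2hc = s2hm * (1.0 - rho**2)
            if s2hc <= 0:
                raise InferenceError(f"non-positive sigma2_hc at rho={rho}")
            P[sl, sl] = self._comp.q_dense(rho, s2hc)
            logdet += self._comp.log_det(rho, s2hc)
        elif self.term == "ih":
            s2 = params["sigma2_I"]
            P[sl, sl] = np.eye(q) / s2
            logdet += -q * math.log(s2)
        else:
            s2 = params["sigma2_v"]
            P[sl, sl] = np.eye(q) / s2
            logdet += -q * math.log(s2)
        if self.sum_to_zero:
            # soft constraint sum(h) ~ N(0, 1e-8)
            ones = np.zeros(m)
            ones[sl] = 1.0
            P += 1e8 * np.outer(ones, ones)
        return P, logdet

    def log_marginal_likelihood(self, theta) -> float:
        """log p(y | theta), the latent field integrated out exactly.

        ``theta`` may be a dict of natural-scale hyper-parameters (e.g.
        ``{"rho": .5, "sigma2_hm": 1., "sigma2_e": 1.}``) or an internal-scale
        vector ordered as ``self.hyper_names``.
        """
        params = self._theta_dict(theta)
        mu, _, logml = self._conditional_core(params, want_cov=False)
        return logml

    def _conditional_core(self, params: dict[str, float], want_cov: bool):
        """Gaussian conditional of the latent field given theta.

        Returns (mean, covariance or diag-variance, log marginal likelihood).
        One Cholesky factorisation of the joint latent precision
        P + W^T W / sigma2_e does all the work; log-determinants come from
        the factor diagonal.
        """
        s2e = params["sigma2_e"]
        P, logdetP = self._prior_precision(params)
        A = P + self._WtW / s2e
        try:
            L = sla.cho_factor(A, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise InferenceError(f"joint precision not PD at theta={params}") \
                from exc
        logdetA = 2.0 * float(np.log(np.diag(L[0])).sum())
        b = self._Wty / s2e
        mu = sla.cho_solve(L, b, check_finite=False)
        p = self.y.size
        logml = (
            -0.5 * p * (_LOG2PI + math.log(s2e))
            + 0.5 * logdetP
            - 0.5 * logdetA
            - 0.5 * (self._yty / s2e - float(b @ mu))
        )
        if want_cov:
            cov = sla.cho_solve(L, np.eye(self.n_latent), check_finite=False)
            return mu, cov, logml
        return mu, None, logml

    def conditional(self, theta):
        """Latent posterior mean and covariance for fixed hyper-parameters."""
        params = self._theta_dict(theta)
        mu, cov, _ = self._conditional_core(params, want_cov=True)
        return mu, cov

    def log_prior_internal(self, theta_internal: np.ndarray) -> float:
        """Log prior density of the hyper-parameters on the internal scale."""
        lp = 0.0
        for name, val in zip(self.hyper_names, theta_internal):
            if name == "rho":
                rho = float(_rho_from_internal(val))
                lp += float(self.priors.rho.log_density(rho))
                lp += math.log((1.0 - rho**2) / 2.0)  # d rho / d internal
            else:
                sigma = math.exp(val / 2.0)
                lp += float(self.priors.sd_prior(name).log_density(sigma))
                lp += math.log(sigma / 2.0)           # d sigma / d log(var)
        return lp

    def log_posterior_internal(self, theta_internal) -> float:
        theta_internal = np.asarray(theta_internal, dtype=float)
        try:
            out = (self.log_marginal_likelihood(theta_internal)
                   + self.log_prior_internal(theta_internal))
        except (InferenceError, OverflowError, ValueError):
            return -np.inf
        return out if np.isfinite(out) else -np.inf

    # -- fitting -----------------------------------------------------------

    def _start_value(self) -> np.ndarray:
        vary = float(np.var(self.y)) if self.y.size > 1 else 1.0
        vary = max(vary, 1e-3)
        start = []
        for name in self.hyper_names:
            if name == "rho":
                start.append(_rho_to_internal(0.5))
            else:
                start.append(math.log(vary / 2.0))
        return np.array(start)

    def fit(
        self,
        grid: Optional[GridSettings] = None,
        start: Optional[np.ndarray] = None,
        store_cov: Optional[bool] = None,
    ) -> "HaplotypeResults":
        """Posterior inference: hyper-parameter grid + exact Gaussian conditionals.

        Finds the posterior mode of the internal-scale hyper-parameters,
        scales a Cartesian grid by the numerical Hessian, prunes low-weight
        points, and mixes the per-point exact Gaussian conditionals of the
        latent field with the normalised grid weights.  Deterministic given
        the model and settings.  A failed mode search is reported through
        ``converged=False`` on the results, not an exception.
        """
        from scipy.optimize import minimize

        settings = grid if grid is not None else GridSettings()
        x0 = np.asarray(start, float) if start is not None \
            else self._start_value()

        neg = lambda t: -self.log_posterior_internal(t)
        res = minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-5,
                     "maxfev": settings.max_opt_iter},
        )
        mode = np.asarray(res.x, dtype=float)
        converged = bool(res.success) and np.isfinite(res.fun)

        sds = self._hessian_sds(mode)
        steps = settings.extent * sds / ((settings.points_per_dim - 1) / 2.0)

        offsets = np.linspace(-settings.extent, settings.extent,
                              settings.points_per_dim)
        axes = [mode[d] + offsets * sds[d] for d in range(self.n_hyper)]
        pts = np.array(list(itertools.product(*axes)))
        logpost = np.array([self.log_posterior_internal(t) for t in pts])
        top = logpost.max()
        if not np.isfinite(top):
            raise InferenceError("all grid points have zero posterior mass")
        keep = logpost > top - settings.prune_log_drop
        pts, logpost = pts[keep], logpost[keep]
        w = np.exp(logpost - top)
        w /= w.sum()

        if store_cov is None:
            store_cov = self.n_latent <= 600

        m = self.n_latent
        mean = np.zeros(m)
        second = np.zeros(m)
        cov_acc = np.zeros((m, m)) if store_cov else None
        for wg, t in zip(w, pts):
            params = self._theta_dict(t)
            mu, cov, _ = self._conditional_core(params, want_cov=True)
            mean += wg * mu
            second += wg * (np.diag(cov) + mu**2)
            if store_cov:
                cov_acc += wg * (cov + np.outer(mu, mu))
        var = np.maximum(second - mean**2, 0.0)
        if store_cov:
            cov_acc -= np.outer(mean, mean)

        natural = {
            name: np.array([self._theta_dict(t)[name] for t in pts])
            for name in self.hyper_names
        }
        log_evidence = top + math.log(np.exp(logpost - top).sum()) \
            + float(np.log(steps).sum())

        return HaplotypeResults(
            model=self,
            latent_mean=mean,
            latent_var=var,
            latent_cov=cov_acc,
            theta_grid_internal=pts,
            theta_grid=natural,
            weights=w,
            grid_steps=steps,
            mode_internal=mode,
            converged=converged,
            log_evidence=log_evidence,
        )

    def _hessian_sds(self, mode: np.ndarray, step: float = 0.1) -> np.ndarray:
        """Per-dimension posterior sds from a finite-difference Hessian."""
        d = self.n_hyper
        f = self.log_posterior_internal
        H = np.zeros((d, d))
        f0 = f(mode)
        for i in range(d):
            ei = np.zeros(d); ei[i] = step
            H[i, i] = (f(mode + ei) - 2 * f0 + f(mode - ei)) / step**2
            for j in range(i + 1, d):
                ej = np.zeros(d); ej[j] = step
                H[i, j] = H[j, i] = (
                    f(mode + ei + ej) - f(mode + ei - ej)
                    - f(mode - ei + ej) + f(mode - ei - ej)
                ) / (4 * step**2)
        sds = np.full(d, 0.5)
        try:
            cov = np.linalg.inv(-H)
            diag = np.diag(cov)
            ok = np.isfinite(diag) & (diag > 0)
            sds[ok] = np.sqrt(diag[ok])
        except np.linalg.LinAlgError:
            dd = -np.diag(H)
            ok = np.isfinite(dd) & (dd > 0)
            sds[ok] = 1.0 / np.sqrt(dd[ok])
        return np.clip(sds, 0.05, 3.0)


@dataclass
class HaplotypeResults:
    """Posterior summaries from :meth:`HaplotypeModel.fit`.

    Latent marginals are Gaussian mixtures over the hyper-parameter grid;
    ``latent_mean``/``latent_var`` are the mixture moments (downstream scoring
    treats each marginal as a Gaussian with these moments).
    """

    model: HaplotypeModel
    latent_mean: np.ndarray
    latent_var: np.ndarray
    latent_cov: Optional[np.ndarray]
    theta_grid_internal: np.ndarray
    theta_grid: dict[str, np.ndarray]
    weights: np.ndarray
    grid_steps: np.ndarray
    mode_internal: np.ndarray
    converged: bool
    log_evidence: float

    # -- latent field ------------------------------------------------------

    @property
    def latent_sd(self) -> np.ndarray:
        return np.sqrt(self.latent_var)

    def haplotype_effects(self, include_phantoms: bool = True) -> pd.DataFrame:
        """Posterior mean/sd per haplotype node (HN/IH) or per site (mutation)."""
        m = self.model
        sl = m.hap_slice
        labels = np.array(m.hap_labels)
        phantom = m.latent_is_phantom[sl]
        nobs = np.zeros(len(labels))
        if m.term == "hn":
            counts = dict(zip(m.haplotype_ids, m.n_phenotypes_per_haplotype))
            nobs = np.array([counts.get(l, 0.0) for l in labels])
        elif m.term == "ih":
            nobs = m.n_phenotypes_per_haplotype
        df = pd.DataFrame({
            "id": labels,
            "mean": self.latent_mean[sl],
            "sd": self.latent_sd[sl],
            "n_phenotypes": nobs,
            "is_phantom": phantom,
        })
        if not include_phantoms:
            df = df[~df["is_phantom"]].reset_index(drop=True)
        return df

    def haplotype_posterior(self, ids: Sequence[str]):
        """Mean vector and mixture covariance of selected haplotype effects."""
        m = self.model
        if m.term == "mutation":
            raise ValueError("mutation-model fits have per-site latent effects; "
                             "use mutation_effects()")
        pos = {l: i for i, l in enumerate(m.hap_labels)}
        idx = np.array([m.hap_slice.start + pos[h] for h in ids])
        mean = self.latent_mean[idx]
        if self.latent_cov is None:
            raise InferenceError("latent covariance was not stored; refit with "
                                 "store_cov=True")
        cov = self.latent_cov[np.ix_(idx, idx)]
        return mean, cov

    # -- derived quantities --------------------------------------------------

    def mutation_effects(self, allele_matrix: Optional[AlleleMatrix] = None,
                         include_phantoms: bool = False) -> pd.DataFrame:
        """Per-mutation posterior mean and sd.

        For a mutation-model fit these are the latent site effects.  For an
        HN/IH fit they are back-solved from the haplotype effects through the
        left inverse v = (U^T U)^{-1} U^T h applied to the posterior of h
        (phantom haplotypes, which have no allele row, are excluded).
        """
        m = self.model
        if m.term == "mutation":
            am = allele_matrix if allele_matrix is not None else m.allele_matrix
            sl = m.hap_slice
            return pd.DataFrame({
                "site": list(am.site_ids),
                "mean": self.latent_mean[sl],
                "sd": self.latent_sd[sl],
            })
        if allele_matrix is None:
            raise ValueError("allele_matrix required to back-solve mutation "
                             "effects from a haplotype fit")
        if include_phantoms:
            scored = [h for h in m.hap_labels]
        else:
            scored = [h for h in allele_matrix.haplotype_ids]
        am = allele_matrix.reindex(scored)
        U = am.U.astype(float)
        utu = U.T @ U
        rank = np.linalg.matrix_rank(U)
        if rank < U.shape[1]:
            # name one set of dependent sites via pivoted QR
            from scipy.linalg import qr

            _, _, piv = qr(U, pivoting=True, mode="economic")
            dependent = [am.site_ids[j] for j in sorted(piv[rank:])]
            raise np.linalg.LinAlgError(
                f"U^T U is rank deficient (rank {rank} < {U.shape[1]}); "
                f"collinear site set: {dependent}"
            )
        M = sla.cho_solve(sla.cho_factor(utu), U.T)   # (U^T U)^{-1} U^T
        h_mean, h_cov = self.haplotype_posterior(scored)
        v_mean = M @ h_mean
        v_var = np.maximum(np.einsum("ij,jk,ik->i", M, h_cov, M), 0.0)
        return pd.DataFrame({
            "site": list(am.site_ids),
            "mean": v_mean,
            "sd": np.sqrt(v_var),
        })

    # -- hyper-parameters ----------------------------------------------------

    def hyper_mean(self, name: str) -> float:
        return float(np.sum(self.weights * self.theta_grid[name]))

    def sample_hyper(self, names: Sequence[str], n_samples: int,
                     seed) -> dict[str, np.ndarray]:
        """Joint posterior samples of hyper-parameters from the grid.

        Grid cells are drawn by weight; within a cell the internal-scale
        value is jittered uniformly over the cell width, smoothing the
        discrete grid into a piecewise-constant density.
        """
        rng = np.random.default_rng(seed)
        dims = [self.model.hyper_names.index(nm) for nm in names]
        cells = rng.choice(len(self.weights), size=n_samples, p=self.weights)
        out = {}
        for nm, d in zip(names, dims):
            internal = self.theta_grid_internal[cells, d]
            internal = internal + rng.uniform(-0.5, 0.5, n_samples) \
                * self.grid_steps[d]
            if nm == "rho":
                out[nm] = np.asarray(_rho_from_internal(internal))
            else:
                out[nm] = np.exp(internal)
        return out

    def _marginal_nodes(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Internal-scale axis values and their marginal masses for one
        hyper-parameter."""
        d = self.model.hyper_names.index(name)
        vals = self.theta_grid_internal[:, d]
        axis = np.unique(vals)
        mass = np.array([self.weights[vals == v].sum() for v in axis])
        return axis, mass

    def marginal_quantiles(self, name: str, probs) -> np.ndarray:
        """Quantiles of a hyper-parameter marginal on the natural scale.

        The discrete grid marginal is smoothed into a continuous density by
        exponential (log-linear) interpolation of the node masses, with
        exponential tails extrapolated beyond the outermost nodes from the
        adjacent slope.  This recovers the tail mass a midpoint rule clips
        on skewed marginals.
        """
        probs = np.atleast_1d(np.asarray(probs, dtype=float))
        axis, mass = self._marginal_nodes(name)
        step = self.grid_steps[self.model.hyper_names.index(name)]
        if axis.size == 1:
            out = np.full(probs.shape, axis[0])
        else:
            logd = np.log(np.maximum(mass, 1e-300))
            # extend 5 steps past each edge with an exponential tail whose
            # decay rate matches the adjacent log-density slope
            decay_lo = max((logd[1] - logd[0]) / (axis[1] - axis[0]),
                           0.2 / step)
            decay_hi = max((logd[-2] - logd[-1]) / (axis[-1] - axis[-2]),
                           0.2 / step)
            ext = 5.0 * step
            axis = np.concatenate([[axis[0] - ext], axis, [axis[-1] + ext]])
            logd = np.concatenate([[logd[0] - decay_lo * ext], logd,
                                   [logd[-1] - decay_hi * ext]])
            seg = np.zeros(axis.size - 1)
            for j in range(seg.size):
                a, b = axis[j], axis[j + 1]
                la, lb = logd[j], logd[j + 1]
                if abs(lb - la) < 1e-12:
                    seg[j] = math.exp(la) * (b - a)
                else:
                    seg[j] = (math.exp(lb) - math.exp(la)) * (b - a) / (lb - la)
            cdf = np.concatenate([[0.0], np.cumsum(seg)])
            total = cdf[-1]
            out = np.empty(probs.shape)
            for i, p in enumerate(probs):
                target = p * total
                j = int(np.searchsorted(cdf, target, side="right") - 1)
                j = min(max(j, 0), seg.size - 1)
                a, b = axis[j], axis[j + 1]
                la, lb = logd[j], logd[j + 1]
                rem = target - cdf[j]
                if abs(lb - la) < 1e-12 or seg[j] <= 0:
                    out[i] = a + (b - a) * (rem / seg[j] if seg[j] > 0 else 0.5)
                else:
                    k = (lb - la) / (b - a)
                    out[i] = a + np.log1p(rem * k / math.exp(la)) / k
        if name == "rho":
            return np.asarray(_rho_from_internal(out))
        return np.exp(out)

    def hyper_interval(self, name: str, level: float = 0.95,
                       **_ignored) -> tuple[float, float]:
        """Central credible interval from the smoothed grid marginal."""
        lo, hi = self.marginal_quantiles(
            name, [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)

    def conditional_variance_posterior(
        self, n_samples: int = 10000, seed=0
    ) -> dict[str, float]:
        """Posterior of sigma2_hc = sigma2_hm (1 - rho^2) by joint sampling."""
        m = self.model
        if m.term != "hn":
            raise ValueError("sigma2_hc is defined only for the HN term")
        if m.rho_fixed is not None:
            s = self.sample_hyper(["sigma2_hm"], n_samples, seed)
            s2hc = s["sigma2_hm"] * (1.0 - m.rho_fixed**2)
        else:
            s = self.sample_hyper(["rho", "sigma2_hm"], n_samples, seed)
            s2hc = s["sigma2_hm"] * (1.0 - s["rho"] ** 2)
        lo, hi = np.quantile(s2hc, [0.025, 0.975])
        return {"mean": float(s2hc.mean()), "lower": float(lo),
                "upper": float(hi)}

    def hyper_summary(self, n_samples: int = 10000, seed=0) -> pd.DataFrame:
        rows = []
        for name in self.model.hyper_names:
            lo, hi = self.hyper_interval(name, n_samples=n_samples, seed=seed)
            rows.append({
                "parameter": name,
                "mean": self.hyper_mean(name),
                "lower95": lo,
                "upper95": hi,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Haplotype effects model",
            "=" * 54,
            f"term: {m.term}    p = {m.y.size}    latent dim = {m.n_latent}",
            f"hyper-parameters: {', '.join(m.hyper_names)}",
            f"grid points kept: {len(self.weights)}    "
            f"converged: {self.converged}",
            f"log evidence (grid): {self.log_evidence:.3f}",
            "",
            "Hyper-parameter posterior",
            "-" * 54,
            self.hyper_summary().to_string(index=False,
                                           float_format=lambda v: f"{v:.4f}"),
        ]
        eff = self.haplotype_effects(include_phantoms=False)
        head = eff.head(10)
        lines += [
            "",
            f"Haplotype effects (first {len(head)} of {len(eff)})",
            "-" * 54,
            head.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


# -- functional aliases matching the operation-style interface ---------------

def assemble_model(y, X, Z, haplotype_term: str, extra_terms=(),
                   priors: Optional[ModelPriors] = None,
                   **kwargs) -> HaplotypeModel:
    """Validate and assemble a phenotype model (functional constructor)."""
    return HaplotypeModel(y, Z, term=haplotype_term, X=X,
                          extra_terms=extra_terms, priors=priors, **kwargs)


def log_marginal_likelihood(model: HaplotypeModel, theta) -> float:
    return model.log_marginal_likelihood(theta)


def fit(model: HaplotypeModel, grid: Optional[GridSettings] = None,
        **kwargs) -> HaplotypeResults:
    return model.fit(grid=grid, **kwargs)


def estimate_mutation_effects(results: HaplotypeResults,
                              allele_matrix: AlleleMatrix) -> pd.DataFrame:
    return results.mutation_effects(allele_matrix)


def derive_conditional_variance_posterior(results: HaplotypeResults,
                                          n_samples: int = 10000,
                                          seed=0) -> dict[str, float]:
    return results.conditional_variance_posterior(n_samples=n_samples,
                                                  seed=seed)
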
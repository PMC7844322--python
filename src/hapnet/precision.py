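"""Sparse AR(1) precision matrices on a haplotype DAG.

The haplotype-network model places a stationary first-order autoregressive
Gaussian process on the DAG: a starting haplotype has the marginal law
N(0, sigma2_hm) and a haplotype with parents h_1..h_k has the conditional law

    h_i | h_1..h_k ~ N((rho/k) * sum_j h_j, sigma2_hc / k),

with sigma2_hc = sigma2_hm * (1 - rho^2).  Writing h = T(rho) eps with
eps ~ N(0, D(rho) sigma2_hc), the joint precision is the very sparse

    Q = (1/sigma2_hc) * T^-T D^-1 T^-1,

which this module assembles directly from the DAG without any matrix
inversion.  T^-1 is unit lower triangular in topological order with entries
-rho/k_i at (child, parent); D^-1 is diagonal with 1 - rho^2 for starting
haplotypes and k_i otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import HaplotypeDAG

__all__ = [
    "ARHyperParams",
    "HNPrecision",
    "PrecisionComponents",
    "precision_components",
    "build_precision",
    "covariance_oracle",
    "build_multiregion_precision",
    "hn_log_det",
]


@dataclass(frozen=True)
class ARHyperParams:
    """AR(1) hyper-parameters: autocorrelation and marginal variance.

    The user-facing parameterisation is (rho, sigma2_hm); the conditional
    (innovation) variance sigma2_hc = sigma2_hm * (1 - rho^2) is derived.
    """

    rho: float
    sigma2_hm: float

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1 for stationarity, got {self.rho}")
        if self.sigma2_hm < 0:
            raise ValueError("sigma2_hm must be >= 0")

    @property
    def sigma2_hc(self) -> float:
        return self.sigma2_hm * (1.0 - self.rho**2)

    @classmethod
    def from_conditional(cls, rho: float, sigma2_hc: float) -> "ARHyperParams":
        if not abs(rho) < 1:
            raise ValueError(f"|rho| must be < 1 for stationarity, got {rho}")
        return cls(rho, sigma2_hc / (1.0 - rho**2))


@dataclass
class HNPrecision:
    """Assembled haplotype-network precision matrix and its factors."""

    Q: sp.csr_matrix
    node_order: list[str]
    params: ARHyperParams
    T_inv: sp.csr_matrix
    D_inv: np.ndarray

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def to_matrix_market(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(path, sp.coo_matrix(self.Q))


@dataclass
class PrecisionComponents:
    """Structural pieces of Q as polynomials in rho.

    sigma2_hc * Q(rho) = Q0 + rho*Q1 + rho^2*Q2 with constant sparse matrices,
    so Q can be re-assembled for many rho values without touching the DAG.
    The diagonal of D^-1 is (1 - rho^2) at starting nodes and k_i elsewhere.
    """

    node_order: list[str]
    is_start: np.ndarray        # bool per node (topo order)
    k: np.ndarray               # parent count per node
    Q0: sp.csr_matrix
    Q1: sp.csr_matrix
    Q2: sp.csr_matrix
    tinv_rows: np.ndarray       # child indices of T^-1 off-diagonal entries
    tinv_cols: np.ndarray       # parent indices
    tinv_coef: np.ndarray       # -1/k_child (multiply by rho)

    @property
    def n(self) -> int:
        return len(self.node_order)

    def q_dense(self, rho: float, sigma2_hc: float) -> np.ndarray:
        """Dense Q(rho)/sigma2_hc for fast small-n work (cached components)."""
        if not hasattr(self, "_dense"):
            self._dense = (self.Q0.toarray(), self.Q1.toarray(),
                           self.Q2.toarray())
        q0, q1, q2 = self._dense
        Q = q0 + rho * q1 + rho**2 * q2
        Q /= sigma2_hc
        return Q

    def q_sparse(self, rho: float, sigma2_hc: float) -> sp.csr_matrix:
        return (self.Q0 + rho * self.Q1 + (rho**2) * self.Q2) / sigma2_hc

    def d_inv(self, rho: float) -> np.ndarray:
        return np.where(self.is_start, 1.0 - rho**2, self.k.astype(float))

    def t_inv(self, rho: float) -> sp.csr_matrix:
        n = self.n
        data = np.concatenate([np.ones(n), rho * self.tinv_coef])
        rows = np.concatenate([np.arange(n), self.tinv_rows])
        cols = np.concatenate([np.arange(n), self.tinv_cols])
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def log_det(self, rho: float, sigma2_hc: float) -> float:
        """log det Q; det T^-1 = 1, so only D^-1 and the scale contribute."""
        return float(np.log(self.d_inv(rho)).sum() - self.n * np.log(sigma2_hc))


def precision_components(dag: HaplotypeDAG) -> PrecisionComponents:
    """Precompute the rho-polynomial structure of Q for a single-mutation DAG.

    Implements the one-pass assembly over haplotypes:
    starting node -> 1 - rho^2 on its diagonal; node i with k_i parents ->
    k_i on its diagonal, -rho at (i, parent), rho^2/k_i on every parent's
    diagonal and between every unordered pair of i's parents.
    """
    if not dag.all_edges_single_mutation():
        raise ValueError(
            "DAG has multi-mutation edges; call insert_phantom_haplotypes first"
        )
    order = list(dag.topo_order)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    k = np.array([dag.parent_count(node) for node in order])
    is_start = k == 0

    r0, c0, v0 = [], [], []   # constant part
    r1, c1, v1 = [], [], []   # linear in rho
    r2, c2, v2 = [], [], []   # quadratic in rho
    tr, tc, tv = [], [], []   # T^-1 off-diagonal structure

    for i, node in enumerate(order):
        ki = k[i]
        if ki == 0:
            r0.append(i); c0.append(i); v0.append(1.0)
            r2.append(i); c2.append(i); v2.append(-1.0)   # 1 - rho^2
            continue
        r0.append(i); c0.append(i); v0.append(float(ki))
        prs = [idx[p] for p in dag.parents[node]]
        for j in prs:
            r1.append(i); c1.append(j); v1.append(-1.0)
            r1.append(j); c1.append(i); v1.append(-1.0)
            r2.append(j); c2.append(j); v2.append(1.0 / ki)
            tr.append(i); tc.append(j); tv.append(-1.0 / ki)
        for a in range(len(prs)):
            for b in range(a + 1, len(prs)):
                r2.append(prs[a]); c2.append(prs[b]); v2.append(1.0 / ki)
                r2.append(prs[b]); c2.append(prs[a]); v2.append(1.0 / ki)

    def mk(r, c, v):
        return sp.csr_matrix((v, (r, c)), shape=(n, n))

    return PrecisionComponents(
        node_order=order,
        is_start=is_start,
        k=k,
        Q0=mk(r0, c0, v0),
        Q1=mk(r1, c1, v1),
        Q2=mk(r2, c2, v2),
        tinv_rows=np.array(tr, dtype=int),
        tinv_cols=np.array(tc, dtype=int),
        tinv_coef=np.array(tv, dtype=float),
    )


def build_precision(dag: HaplotypeDAG, params: ARHyperParams) -> HNPrecision:
    """Assemble the sparse haplotype-effect precision matrix Q.

    Requires every edge to carry exactly one mutation (insert phantom
    haplotypes first).  Q is symmetric positive definite for |rho| < 1 and
    sigma2_hc > 0; its sparsity pattern touches only (node, node),
    (node, parent) and (parent, co-parent) pairs.
    """
    if params.sigma2_hc <= 0:
        raise ValueError("sigma2_hc must be > 0")
    comp = precision_components(dag)
    Q = comp.q_sparse(params.rho, params.sigma2_hc)
    return HNPrecision(
        Q=Q,
        node_order=comp.node_order,
        params=params,
        T_inv=comp.t_inv(params.rho),
        D_inv=comp.d_inv(params.rho),
    )


def covariance_oracle(dag: HaplotypeDAG, params: ARHyperParams) -> np.ndarray:
    """Dense covariance V_h = T D T^T sigma2_hc, for test-scale DAGs only.

    Built by explicitly inverting the unit-triangular T^-1; O(n^3) and meant
    purely as an independent oracle against :func:`build_precision`.
    """
    comp = precision_components(dag)
    if comp.n > 2000:
        raise ValueError("covariance_oracle is a dense test oracle; n too large")
    t_inv = comp.t_inv(params.rho).toarray()
    T = np.linalg.inv(t_inv)
    D = 1.0 / comp.d_inv(params.rho)
    return (T * D) @ T.T * params.sigma2_hc


def build_multiregion_precision(
    dags: list[HaplotypeDAG], params: ARHyperParams
) -> HNPrecision:
    """Block-diagonal Q over several genome regions with shared (rho, sigma2_hc).

    Each region gets its own haplotype-network block; a haplotype's total
    effect is the sum of its per-region segment effects.  Node order is the
    concatenation of per-region topological orders (region labels prefixed
    when regions share haplotype names).
    """
    if not dags:
        raise ValueError("need at least one region DAG")
    blocks = [build_precision(dag, params) for dag in dags]
    order: list[str] = []
    seen: set[str] = set()
    for r, blk in enumerate(blocks):
        for node in blk.node_order:
            name = node if node not in seen else f"region{r}:{node}"
            order.append(name)
        seen.update(blk.node_order)
    return HNPrecision(
        Q=sp.block_diag([b.Q for b in blocks], format="csr"),
        node_order=order,
        params=params,
        T_inv=sp.block_diag([b.T_inv for b in blocks], format="csr"),
        D_inv=np.concatenate([b.D_inv for b in blocks]),
    )


def hn_log_det(comp: PrecisionComponents, rho: float, sigma2_hc: float) -> float:
    """log det of the haplotype-network precision (exact, factorisation-free)."""
    return comp.log_det(rho, sigma2_hc)
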
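"""Synthetic phylogenies, haplotype effects and phenotypes.

Two generative models are provided, matching the two simulation designs the
package is evaluated against:

* the haplotype-network (HN) model: effects drawn along the DAG by ancestral
  recursion from the stationary AR(1) law, with conditional variance fixed to
  sigma2_hc = 1 so residual-variance ratios translate directly into
  sigma2_e in {0.5, 1, 2};
* the mutation model: per-site effects drawn from a spike-and-slab mixture
  (causal with probability lambda), haplotype effects h = U v rescaled so the
  sample variance of h is exactly 1.

Phenotypes are haploid: y = Z h + e with one carried haplotype per
individual.  Two observation designs are supported: ``all_observed`` (every
haplotype carried; a random 15% by exactly one individual each) and
``some_unobserved`` (a random 15% of haplotypes with no phenotyped carrier).
All randomness flows from a single seed via numpy SeedSequence substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .graph import AlleleMatrix, HaplotypeDAG

__all__ = [
    "SimulatedDataset",
    "generate_random_phylogeny",
    "simulate_from_hn",
    "simulate_from_mutation_model",
    "SINGLETON_FRACTION",
    "UNOBSERVED_FRACTION",
]

SINGLETON_FRACTION = 0.15
UNOBSERVED_FRACTION = 0.15

_SCENARIOS = ("all_observed", "some_unobserved")


@dataclass
class SimulatedDataset:
    """One simulated phenotype data set with its generative truth."""

    dag: HaplotypeDAG
    U: Optional[AlleleMatrix]
    true_h: np.ndarray            # per haplotype, in haplotype_ids order
    haplotype_ids: list[str]
    Z: np.ndarray                 # p x n incidence over haplotype_ids
    y: np.ndarray
    e: np.ndarray
    scenario: str
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None
    true_v: Optional[np.ndarray] = None      # mutation model only
    epsilon: Optional[np.ndarray] = None     # HN innovations

    def __post_init__(self) -> None:
        assert np.allclose(self.y, self.Z @ self.true_h + self.e)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def generate_random_phylogeny(
    n_haplotypes: int, seed
) -> tuple[HaplotypeDAG, AlleleMatrix]:
    """Random single-root phylogeny under an infinite-sites scheme.

    Haplotypes are built by sequential random attachment: each new haplotype
    copies a uniformly chosen existing haplotype and gains one newly mutated
    site, giving n haplotypes, n - 1 segregating sites, and every edge exactly
    one mutation.  Deterministic per seed.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    rng = _rng(seed)
    n = n_haplotypes
    labels = [f"H{i:03d}" for i in range(n)]
    parents: dict[str, list[str]] = {labels[0]: []}
    edge_mutations: dict[tuple[str, str], int] = {}
    U = np.zeros((n, n - 1), dtype=np.int8)
    for i in range(1, n):
        j = int(rng.integers(0, i))
        parents[labels[i]] = [labels[j]]
        edge_mutations[(labels[i], labels[j])] = 1
        U[i] = U[j]
        U[i, i - 1] = 1            # site i-1 arises on this haplotype
    dag = HaplotypeDAG(labels, parents, edge_mutations)
    sites = [f"s{i + 1}" for i in range(n - 1)]
    return dag, AlleleMatrix(U, sites, labels)


def _draw_hn_effects(dag: HaplotypeDAG, rho: float, sigma2_hc: float,
                     rng: np.random.Generator) -> dict[str, float]:
    """Ancestral recursion: root ~ N(0, sigma2_hm); child given its k parents
    ~ N(rho * mean(parents), sigma2_hc / k)."""
    sigma2_hm = sigma2_hc / (1.0 - rho**2)
    h: dict[str, float] = {}
    for node in dag.topo_order:
        prs = dag.parents[node]
        if not prs:
            h[node] = rng.normal(0.0, np.sqrt(sigma2_hm))
        else:
            k = len(prs)
            mean = rho * np.mean([h[p] for p in prs])
            h[node] = rng.normal(mean, np.sqrt(sigma2_hc / k))
    return h


def _build_incidence(n: int, p: int, scenario: str,
                     rng: np.random.Generator) -> np.ndarray:
    """Haploid incidence matrix implementing the two observation designs.

    all_observed: exactly round(0.15 n) singleton haplotypes carried by one
    individual each; every other haplotype gets at least two carriers
    (double round-robin, then uniform fill), so the singleton quota is exact.

    some_unobserved: exactly round(0.15 n) haplotypes get no carrier; the
    rest are covered round-robin then filled uniformly.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"scenario must be one of {_SCENARIOS}")
    if scenario == "all_observed":
        n_special = int(round(SINGLETON_FRACTION * n))
        if p < 2 * n - n_special:
            raise ValueError(
                f"all_observed needs p >= {2 * n - n_special} individuals for "
                f"n={n} haplotypes (one per singleton, two or more per "
                f"remaining haplotype); got p={p}"
            )
    else:
        n_special = int(round(UNOBSERVED_FRACTION * n))
        if p < n - n_special:
            raise ValueError("not enough individuals to cover the observed "
                             f"haplotypes (p={p}, n_observed={n - n_special})")
    special = rng.choice(n, size=n_special, replace=False)
    rest = np.setdiff1d(np.arange(n), special)

    assignment = np.empty(p, dtype=int)
    pos = 0
    if scenario == "all_observed":
        assignment[pos:pos + n_special] = special
        pos += n_special
        # two guaranteed carriers per non-singleton haplotype
        assignment[pos:pos + rest.size] = rest
        pos += rest.size
    # one guaranteed carrier per remaining haplotype, then uniform fill
    assignment[pos:pos + rest.size] = rest
    pos += rest.size
    if pos < p:
        assignment[pos:] = rng.choice(rest, size=p - pos, replace=True)
    rng.shuffle(assignment)

    Z = np.zeros((p, n))
    Z[np.arange(p), assignment] = 1.0
    return Z


def simulate_from_hn(
    dag: HaplotypeDAG,
    rho: float,
    ve_over_vhc: float,
    p: int,
    scenario: str = "all_observed",
    seed=None,
    U: Optional[AlleleMatrix] = None,
) -> SimulatedDataset:
    """Simulate phenotypes from the haplotype-network model.

    Haplotype effects follow the stationary AR(1) law on the DAG with
    sigma2_hc = 1 by convention, so ``ve_over_vhc`` is the residual variance
    sigma2_e directly.  Phenotypes are y = Z h + e over the non-phantom
    haplotypes.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if ve_over_vhc <= 0:
        raise ValueError("ve_over_vhc must be > 0")
    ss = _seed_seq(seed)
    rng_h, rng_z, rng_e = (_rng(s) for s in ss.spawn(3))

    h_all = _draw_hn_effects(dag, rho, 1.0, rng_h)
    named = [nd for nd in dag.topo_order if not dag.is_phantom[nd]]
    h = np.array([h_all[nd] for nd in named])

    Z = _build_incidence(len(named), p, scenario, rng_z)
    sigma2_e = ve_over_vhc
    e = rng_e.normal(0.0, np.sqrt(sigma2_e), size=p)
    y = Z @ h + e

    return SimulatedDataset(
        dag=dag, U=U, true_h=h, haplotype_ids=named, Z=Z, y=y, e=e,
        scenario=scenario,
        params={"model": "hn", "rho": rho, "sigma2_hc": 1.0,
                "sigma2_hm": 1.0 / (1 - rho**2), "sigma2_e": sigma2_e},
        seed=seed,
        epsilon=np.array([h_all[nd] for nd in dag.topo_order]),
    )


def simulate_from_mutation_model(
    dag: HaplotypeDAG,
    U: AlleleMatrix,
    lam: float,
    sigma2_e: float,
    p: int,
    scenario: str = "all_observed",
    seed=None,
) -> SimulatedDataset:
    """Simulate phenotypes from the spike-and-slab mutation model.

    Each site is causal with probability ``lam``; causal effects are Gaussian.
    The effect vector is rescaled so the sample variance of h = U v across
    haplotypes is exactly 1, after which y = Z h + e with
    e ~ N(0, I sigma2_e).
    """
    if not 0 < lam <= 1:
        raise ValueError("lam must be in (0, 1]")
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be > 0")
    ss = _seed_seq(seed)
    rng_v, rng_z, rng_e = (_rng(s) for s in ss.spawn(3))

    named = [nd for nd in dag.topo_order if not dag.is_phantom[nd]]
    am = U.reindex(named)
    n_sites = am.U.shape[1]

    for _ in range(100):
        causal = rng_v.random(n_sites) < lam
        if causal.any():
            break
    else:
        raise RuntimeError("no causal site drawn in 100 attempts; "
                           "lambda too small for this site count")
    v = np.where(causal, rng_v.normal(0.0, 1.0, size=n_sites), 0.0)
    h = am.U.astype(float) @ v
    sd_h = np.std(h, ddof=1)
    if sd_h == 0:
        raise RuntimeError("degenerate draw: haplotype effects constant")
    v = v / sd_h
    h = h / sd_h

    Z = _build_incidence(len(named), p, scenario, rng_z)
    e = rng_e.normal(0.0, np.sqrt(sigma2_e), size=p)
    y = Z @ h + e

    return SimulatedDataset(
        dag=dag, U=am, true_h=h, haplotype_ids=named, Z=Z, y=y, e=e,
        scenario=scenario,
        params={"model": "mutation", "lambda": lam, "sigma2_e": sigma2_e,
                "n_causal": int(causal.sum())},
        seed=seed,
        true_v=v,
    )
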
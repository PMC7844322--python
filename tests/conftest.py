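import numpy as np
import pandas as pd
import pytest

import hapnet as hn


def fig1_edge_table() -> pd.DataFrame:
    """The worked-example phylogeny: 10 haplotypes, single starting node i.

    The two identical haplotypes of the source table are merged into one node
    (repeated identical haplotypes are handled as the same haplotype); g' and
    h' are the intermediate haplotypes on the two-mutation paths.
    """
    rows = [
        ("g'", "i", 1), ("g", "g'", 1),
        ("a", "g", 1), ("f", "g", 1), ("b", "g", 1),
        ("h'", "i", 1), ("h", "h'", 1), ("d", "h'", 1),
        ("e", "h", 1),
    ]
    return pd.DataFrame(rows, columns=["child", "parent", "n_mutations"])


@pytest.fixture
def fig1_dag() -> hn.HaplotypeDAG:
    return hn.parse_dag(fig1_edge_table())


@pytest.fixture
def chain3() -> hn.HaplotypeDAG:
    df = pd.DataFrame({"child": ["i", "j", "k"], "parent": ["", "i", "j"]})
    return hn.parse_dag(df)


@pytest.fixture
def star_dag() -> hn.HaplotypeDAG:
    """Node d with three independent starting parents a, b, c."""
    df = pd.DataFrame({
        "child": ["a", "b", "c", "d", "d", "d"],
        "parent": ["", "", "", "a", "b", "c"],
    })
    return hn.parse_dag(df)


@pytest.fixture
def table1_alleles() -> hn.AlleleMatrix:
    """Five distinct haplotypes spanning seven biallelic sites."""
    U = np.array([
        [0, 0, 0, 0, 0, 0, 0],   # ancestral
        [1, 0, 0, 1, 1, 0, 0],
        [1, 0, 0, 0, 1, 1, 0],
        [0, 1, 0, 0, 0, 0, 1],
        [0, 1, 1, 0, 0, 0, 1],
    ])
    return hn.AlleleMatrix(U, [f"s{j}" for j in range(1, 8)],
                           ["i", "a", "b", "d", "e"])


def make_random_dag(rng: np.random.Generator, n_max: int = 12,
                    multi_parent: bool = True) -> hn.HaplotypeDAG:
    """Random single-mutation DAG with optional multi-parent nodes."""
    n = int(rng.integers(2, n_max + 1))
    labels = [f"n{i}" for i in range(n)]
    parents = {}
    for i, lab in enumerate(labels):
        if i == 0 or (i > 0 and rng.random() < 0.1):
            parents[lab] = []
            continue
        k = 1
        if multi_parent and i >= 2 and rng.random() < 0.3:
            k = int(rng.integers(2, min(i, 3) + 1))
        ps = rng.choice(i, size=k, replace=False)
        parents[lab] = [labels[j] for j in sorted(ps)]
    edges = {(c, p): 1 for c, ps in parents.items() for p in ps}
    return hn.HaplotypeDAG(labels, parents, edges)


def make_random_tree(rng: np.random.Generator, n_max: int = 12) -> hn.HaplotypeDAG:
    """Random single-parent DAG (a tree rooted at one starting haplotype)."""
    n = int(rng.integers(2, n_max + 1))
    labels = [f"n{i}" for i in range(n)]
    parents = {labels[0]: []}
    for i in range(1, n):
        parents[labels[i]] = [labels[int(rng.integers(0, i))]]
    edges = {(c, ps[0]): 1 for c, ps in parents.items() if ps}
    return hn.HaplotypeDAG(labels, parents, edges)
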
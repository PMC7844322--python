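"""Phylogenetic DAGs of haplotypes.

A haplotype phylogeny is represented as a directed acyclic graph whose nodes
are haplotypes and whose edges connect each haplotype to the parental
haplotype(s) it derives from by mutation.  Edges carry the number of mutations
separating the pair; the autoregressive model downstream requires every edge
to represent exactly one mutation, which is achieved by inserting unobserved
"phantom" haplotypes along multi-mutation edges.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeDAG",
    "AlleleMatrix",
    "CycleError",
    "parse_dag",
    "write_dag",
    "insert_phantom_haplotypes",
    "dag_from_tree",
]


class CycleError(ValueError):
    """The edge list contains a directed cycle."""


@dataclass
class HaplotypeDAG:
    """A validated phylogenetic DAG of haplotypes.

    Parameters
    ----------
    node_ids
        Haplotype labels in first-appearance order.
    parents
        Map from node to its (possibly empty) list of parental haplotypes.
        Nodes with no parents form the "starting" set and receive the
        stationary marginal distribution in the AR(1) model.
    edge_mutations
        Map ``(child, parent) -> m`` with ``m >= 1`` mutations on the edge.
    is_phantom
        Flags nodes inserted to break multi-mutation edges.
    """

    node_ids: list[str]
    parents: dict[str, list[str]]
    edge_mutations: dict[tuple[str, str], int]
    is_phantom: dict[str, bool] = field(default_factory=dict)
    topo_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_ids:
            raise ValueError("DAG has no nodes (no starting haplotype)")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node labels")
        nodes = set(self.node_ids)
        for child, prs in self.parents.items():
            if child not in nodes:
                raise KeyError(f"parents given for unknown node {child!r}")
            for pr in prs:
                if pr not in nodes:
                    raise KeyError(
                        f"node {child!r} references unknown parent {pr!r}"
                    )
            if len(set(prs)) != len(prs):
                raise ValueError(f"node {child!r} lists a parent twice")
        for node in self.node_ids:
            self.parents.setdefault(node, [])
            self.is_phantom.setdefault(node, False)
        for (child, pr), m in self.edge_mutations.items():
            if pr not in self.parents.get(child, []):
                raise KeyError(f"mutation count for non-edge ({child!r}, {pr!r})")
            if not (isinstance(m, (int, np.integer)) and m >= 1):
                raise ValueError(f"edge ({child!r}, {pr!r}) has non-positive "
                                 f"or non-integer mutation count {m!r}")
        for child, prs in self.parents.items():
            for pr in prs:
                self.edge_mutations.setdefault((child, pr), 1)
        if not self.topo_order:
            self.topo_order = self._compute_topo_order()
        else:
            self._check_topo_order()
        if not self.starting_set:  # unreachable for an acyclic graph
            raise ValueError("no starting haplotype (every node has a parent)")

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def starting_set(self) -> list[str]:
        return [n for n in self.node_ids if not self.parents[n]]

    def parent_count(self, node: str) -> int:
        return len(self.parents[node])

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with parent -> child edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        for child, prs in self.parents.items():
            for pr in prs:
                g.add_edge(pr, child, n_mutations=self.edge_mutations[(child, pr)])
        return g

    def _compute_topo_order(self) -> list[str]:
        # lexicographic tie-break keyed by first-appearance rank: canonical
        # (row-order independent) yet respecting the declared node order
        g = self.to_networkx()
        rank = {n: i for i, n in enumerate(self.node_ids)}
        try:
            return list(nx.lexicographical_topological_sort(
                g, key=lambda n: rank[n]))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise CycleError(f"cycle detected: {path}") from None

    def _check_topo_order(self) -> None:
        if sorted(self.topo_order) != sorted(self.node_ids):
            raise ValueError("topo_order is not a permutation of node_ids")
        pos = {n: i for i, n in enumerate(self.topo_order)}
        for child, prs in self.parents.items():
            for pr in prs:
                if pos[pr] >= pos[child]:
                    raise CycleError(
                        f"topo_order violated: parent {pr!r} after child {child!r}"
                    )

    def all_edges_single_mutation(self) -> bool:
        return all(m == 1 for m in self.edge_mutations.values())

    def __eq__(self, other: object) -> bool:
        """Structural equality: same nodes, parents, mutation counts and
        phantom flags (node declaration order is presentation, not
        structure)."""
        if not isinstance(other, HaplotypeDAG):
            return NotImplemented
        return (
            set(self.node_ids) == set(other.node_ids)
            and {k: sorted(v) for k, v in self.parents.items()}
            == {k: sorted(v) for k, v in other.parents.items()}
            and self.edge_mutations == other.edge_mutations
            and self.is_phantom == other.is_phantom
        )


@dataclass
class AlleleMatrix:
    """Haplotype x site 0/1 allele matrix (0 = ancestral/reference allele)."""

    U: np.ndarray
    site_ids: list[str]
    haplotype_ids: list[str]

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U)
        if self.U.ndim != 2:
            raise ValueError("U must be 2-dimensional")
        if self.U.shape != (len(self.haplotype_ids), len(self.site_ids)):
            raise ValueError("U shape does not match haplotype/site ids")
        if not np.isin(self.U, (0, 1)).all():
            raise ValueError("allele matrix entries must be 0/1")
        _, counts = np.unique(self.U, axis=0, return_counts=True)
        if (counts > 1).any():
            raise ValueError("duplicated haplotype rows among named haplotypes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.U, index=self.haplotype_ids, columns=self.site_ids)

    def reindex(self, haplotype_ids: list[str]) -> "AlleleMatrix":
        """Reorder rows to a given haplotype order (all ids must be present)."""
        pos = {h: i for i, h in enumerate(self.haplotype_ids)}
        idx = [pos[h] for h in haplotype_ids]
        return AlleleMatrix(self.U[idx], list(self.site_ids), list(haplotype_ids))


def parse_dag(edge_table) -> HaplotypeDAG:
    """Parse a child/parent/n_mutations edge table into a :class:`HaplotypeDAG`.

    ``edge_table`` may be a pandas DataFrame, a path to a TSV file, or a
    file-like object.  An empty/missing parent marks a starting haplotype.
    Multi-parent nodes occupy several rows.  Node order is first-appearance
    order (scanning child then parent within each row).
    """
    df = _as_edge_frame(edge_table)
    if df.empty:
        raise ValueError("empty edge table: no starting haplotype")
    if "child" not in df.columns or "parent" not in df.columns:
        raise ValueError("edge table must have columns 'child' and 'parent'")
    has_mut = "n_mutations" in df.columns
    has_phantom = "is_phantom" in df.columns

    node_ids: list[str] = []
    seen: set[str] = set()
    parents: dict[str, list[str]] = {}
    edge_mutations: dict[tuple[str, str], int] = {}
    is_phantom: dict[str, bool] = {}

    def _add(node: str) -> None:
        if node not in seen:
            seen.add(node)
            node_ids.append(node)
            parents.setdefault(node, [])

    for row in df.itertuples(index=False):
        child = str(row.child).strip()
        if not child or child.lower() == "nan":
            raise ValueError("row with empty child label")
        _add(child)
        if has_phantom:
            is_phantom[child] = bool(int(getattr(row, "is_phantom")))
        raw_parent = getattr(row, "parent")
        parent = "" if pd.isna(raw_parent) else str(raw_parent).strip()
        if not parent:
            continue  # starting haplotype row
        _add(parent)
        if parent in parents[child]:
            raise ValueError(f"duplicate edge {child!r} -> {parent!r}")
        parents[child].append(parent)
        m = 1
        if has_mut:
            raw_m = getattr(row, "n_mutations")
            if not pd.isna(raw_m):
                fm = float(raw_m)
                if fm != int(fm) or int(fm) < 1:
                    raise ValueError(
                        f"edge ({child!r}, {parent!r}): mutation count must be a "
                        f"positive integer, got {raw_m!r}"
                    )
                m = int(fm)
        edge_mutations[(child, parent)] = m

    return HaplotypeDAG(node_ids, parents, edge_mutations, is_phantom)


def _as_edge_frame(edge_table) -> pd.DataFrame:
    if isinstance(edge_table, pd.DataFrame):
        return edge_table
    if isinstance(edge_table, (str, os.PathLike)):
        return pd.read_csv(edge_table, sep="\t", dtype=str)
    if isinstance(edge_table, io.IOBase) or hasattr(edge_table, "read"):
        return pd.read_csv(edge_table, sep="\t", dtype=str)
    raise TypeError(f"cannot read edge table from {type(edge_table)!r}")


def write_dag(dag: HaplotypeDAG, path) -> None:
    """Write a DAG as a TSV edge list (round-trips through :func:`parse_dag`)."""
    rows = []
    for node in dag.node_ids:
        prs = dag.parents[node]
        if not prs:
            rows.append((node, "", "", int(dag.is_phantom[node])))
        for pr in prs:
            rows.append((node, pr, dag.edge_mutations[(node, pr)],
                         int(dag.is_phantom[node])))
    df = pd.DataFrame(rows, columns=["child", "parent", "n_mutations", "is_phantom"])
    df.to_csv(path, sep="\t", index=False)


def insert_phantom_haplotypes(dag: HaplotypeDAG) -> HaplotypeDAG:
    """Expand every multi-mutation edge into a chain of single-mutation edges.

    An edge carrying ``m > 1`` mutations between parent and child is replaced
    by ``m - 1`` phantom haplotypes labelled ``child.p1, child.p2, ...``
    ordered from parent toward child.  Only the path length between named
    haplotypes matters to the AR(1) model, so assigning mutations to phantoms
    in an arbitrary linear order is innocuous.  Idempotent.
    """
    if dag.all_edges_single_mutation():
        return dag

    node_ids = list(dag.node_ids)
    parents = {n: list(ps) for n, ps in dag.parents.items()}
    edge_mutations = dict(dag.edge_mutations)
    is_phantom = dict(dag.is_phantom)
    existing = set(node_ids)

    for (child, pr), m in sorted(dag.edge_mutations.items()):
        if m == 1:
            continue
        # one phantom chain per (child, parent) edge; suffix disambiguates
        # multi-parent children with several multi-mutation edges
        multi = sum(v > 1 for (c, _), v in dag.edge_mutations.items() if c == child)
        tag = f"{child}.p" if multi == 1 else f"{child}.{pr}.p"
        labels = [f"{tag}{j}" for j in range(1, m)]
        for lab in labels:
            if lab in existing:
                raise ValueError(f"phantom label {lab!r} collides with a node")
            existing.add(lab)
        node_ids.extend(labels)
        chain = [pr, *labels, child]
        parents[child].remove(pr)
        del edge_mutations[(child, pr)]
        for lab in labels:
            parents[lab] = []
            is_phantom[lab] = True
        for a, b in zip(chain[:-1], chain[1:]):
            parents[b].append(a)
            edge_mutations[(b, a)] = 1

    return HaplotypeDAG(node_ids, parents, edge_mutations, is_phantom)


def dag_from_tree(newick_text: str) -> HaplotypeDAG:
    """Build a DAG from a Newick tree; branch lengths count mutations.

    Internal and leaf nodes all become haplotypes; the root is the starting
    haplotype.  Branch lengths must be positive integers (mutation counts,
    default 1 when absent) -- the model counts mutations and does not use
    continuous branch lengths.
    """
    import dendropy

    try:
        tree = dendropy.Tree.get(data=newick_text, schema="newick",
                                 suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    node_ids: list[str] = []
    parents: dict[str, list[str]] = {}
    edge_mutations: dict[tuple[str, str], int] = {}
    counter = 0

    def label(nd) -> str:
        nonlocal counter
        if nd.taxon is not None and nd.taxon.label:
            return nd.taxon.label
        if nd.label:
            return nd.label
        counter += 1
        return "root" if nd.parent_node is None else f"node{counter}"

    names: dict[int, str] = {}
    for nd in tree.preorder_node_iter():
        name = label(nd)
        if name in parents:
            raise ValueError(f"duplicate node label {name!r} in tree")
        names[id(nd)] = name
        node_ids.append(name)
        parents[name] = []
        if nd.parent_node is not None:
            pr = names[id(nd.parent_node)]
            parents[name].append(pr)
            bl = nd.edge.length
            m = 1 if bl is None else float(bl)
            if m != int(m) or int(m) < 1:
                raise ValueError(
                    f"branch length {bl!r} on edge to {name!r} is not a "
                    "positive integer mutation count"
                )
            edge_mutations[(name, pr)] = int(m)

    return HaplotypeDAG(node_ids, parents, edge_mutations)
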
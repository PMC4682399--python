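"""ARG data model, validation, and degree-based node classification.

An ancestral recombination graph (ARG) is represented as a directed acyclic
graph whose edges point from ancestor to descendant.  Leaves (out-degree 0)
carry haplotype labels identifying the sampled chromosomes.  Reconstructed
ARGs are typically *partial* (subARGs) and may have several roots; both are
supported here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger("argwalker")

__all__ = [
    "ArgGraph",
    "NodeClassification",
    "ArgValidationError",
    "NotADagError",
    "load_arg",
    "classify_nodes",
    "read_edge_list",
    "read_leaf_labels",
    "write_edge_list",
    "write_leaf_labels",
]


class ArgValidationError(ValueError):
    """Raised when an edge list or label map violates the ARG data model."""


class NotADagError(ArgValidationError):
    """Raised when the directed graph contains a cycle."""


@dataclass(frozen=True)
class ArgGraph:
    """A validated ancestor→descendant DAG with labelled sample leaves.

    Attributes
    ----------
    node_ids : tuple of int
        All node ids, sorted.  Ids need not be contiguous.
    edges : tuple of (int, int)
        Directed edges ``(ancestor, descendant)``, sorted, without duplicates.
    leaf_labels : dict
        Map from leaf node id to haplotype identifier (string).
    """

    node_ids: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    leaf_labels: dict[int, str]
    _index: dict[int, int] = field(repr=False, compare=False, default_factory=dict)

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self.node_ids)

    def index_of(self, node_id: int) -> int:
        """Dense 0-based index of ``node_id`` (stable id↔index map)."""
        return self._index[node_id]

    def out_edges(self, node_id: int) -> list[tuple[int, int]]:
        return [e for e in self.edges if e[0] == node_id]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class NodeClassification:
    """Partition of ARG nodes into roots, recombination nodes, leaves, other.

    Roots have in-degree 0 and out-degree > 0; recombination nodes have
    in-degree ≥ 2 and out-degree > 0; leaves have in-degree > 0 and
    out-degree 0.  Everything else (internal coalescent nodes, isolated
    nodes) lands in ``other``.
    """

    roots: frozenset[int]
    recombination_nodes: frozenset[int]
    leaves: frozenset[int]
    other: frozenset[int]


def load_arg(
    edge_records: Iterable[tuple[int, int]],
    leaf_labels: Mapping[int, str] | None = None,
    *,
    reverse: bool = False,
) -> ArgGraph:
    """Build and validate an :class:`ArgGraph` from an edge list.

    Parameters
    ----------
    edge_records
        ``(ancestor, descendant)`` pairs.  With ``reverse=True`` the input
        is interpreted as descendant→ancestor and flipped.
    leaf_labels
        Map from leaf node id to haplotype identifier.  Labelled nodes must
        be sinks (out-degree 0).
    reverse
        Accept descendant→ancestor edge lists from converters that emit
        child-first records.

    Raises
    ------
    NotADagError
        If the graph contains a directed cycle (one cycle edge is named).
    ArgValidationError
        On self-loops, duplicate edges, unparseable ids, or a label placed
        on a non-sink node.
    """
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for rec in edge_records:
        try:
            u, v = int(rec[0]), int(rec[1])
        except (TypeError, ValueError) as exc:
            raise ArgValidationError(f"edge ids must be integers, got {rec!r}") from exc
        if reverse:
            u, v = v, u
        if u == v:
            raise ArgValidationError(f"self-loop on node {u}")
        if (u, v) in seen:
            raise ArgValidationError(f"duplicate edge ({u}, {v})")
        seen.add((u, v))
        edges.append((u, v))
    if not edges and not leaf_labels:
        raise ArgValidationError("empty ARG: no edges and no labelled leaves")

    labels = {int(k): str(v) for k, v in (leaf_labels or {}).items()}
    nodes = sorted({u for u, _ in edges} | {v for _, v in edges} | set(labels))

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise NotADagError(f"not a DAG: cycle through edge {cyc[0][:2]}")
    for node in labels:
        if g.out_degree(node) != 0:
            raise ArgValidationError(
                f"label {labels[node]!r} on non-sink node {node} (out-degree "
                f"{g.out_degree(node)})"
            )
    index = {nid: i for i, nid in enumerate(nodes)}
    return ArgGraph(tuple(nodes), tuple(sorted(edges)), labels, index)


def classify_nodes(g: ArgGraph) -> NodeClassification:
    """Classify nodes by degree into roots, recombination nodes and leaves.

    Classification is total: isolated nodes (degree 0) are reported in
    ``other`` with a warning, as are ordinary internal coalescent nodes
    (in-degree 1, out-degree ≥ 1).
    """
    dg = g.to_networkx()
    roots, recomb, leaves, other = set(), set(), set(), set()
    for node in g.node_ids:
        din, dout = dg.in_degree(node), dg.out_degree(node)
        if din == 0 and dout > 0:
            roots.add(node)
        elif din >= 2 and dout > 0:
            recomb.add(node)
        elif din > 0 and dout == 0:
            leaves.add(node)
        else:
            if din == 0 and dout == 0:
                warnings.warn(f"isolated node {node} (degree 0) classified as 'other'")
            other.add(node)
    return NodeClassification(
        frozenset(roots), frozenset(recomb), frozenset(leaves), frozenset(other)
    )


# ---------------------------------------------------------------- file I/O
#
# Edge-list format: TSV, one edge per line "parent<TAB>child" with an
# optional third annotation column; '#' starts a comment.  Companion
# leaf-label file: "node_id<TAB>haplotype_id".  External reconstruction
# output (e.g. IRiS) is consumed by converting it to this edge list.


def read_edge_list(path) -> list[tuple[int, int]]:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ArgValidationError(f"{path}:{lineno}: expected 'parent<TAB>child'")
            try:
                edges.append((int(parts[0]), int(parts[1])))
            except ValueError as exc:
                raise ArgValidationError(f"{path}:{lineno}: non-integer node id") from exc
    return edges


def read_leaf_labels(path) -> dict[int, str]:
    labels: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ArgValidationError(
                    f"{path}:{lineno}: expected 'node_id<TAB>haplotype_id'"
                )
            labels[int(parts[0])] = parts[1]
    return labels


def write_edge_list(g: ArgGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# parent\tchild\n")
        for u, v in g.edges:
            fh.write(f"{u}\t{v}\n")


def write_leaf_labels(g: ArgGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# node_id\thaplotype_id\n")
        for node in sorted(g.leaf_labels):
            fh.write(f"{node}\t{g.leaf_labels[node]}\n")
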
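"""Backward/forward random-walk engine on ancestral recombination graphs.

The walker turns ARG topology into per-haplotype recombination strengths in
three deterministic steps (despite the name, nothing is sampled):

1. *Backward walk* — each edge ``u→v`` receives an integer weight equal to
   the number of descendants of ``v`` counted with path multiplicity, plus
   one:  ``W(u→v) = 1 + Σ_{(v,w)∈E} W(v→w)``.  A recombination node that is
   reachable along two paths is counted twice, so edges whose subtrees are
   rich in recombination nodes collect larger weights.
2. *Normalization* — weights are row-normalized into a transition matrix
   ``T(u→v) = W(u→v) / Σ_k W(u→k)``; leaves are absorbing.
3. *Forward walk* — signal mass ``I`` is placed on the roots (each root gets
   the sum of its outgoing weights) and propagated by iterating
   ``I ← I·T`` and ``V_L ← V_L + I`` until no mass remains in transit.  The
   mass absorbed at the labelled leaves is the strength profile ``V_L``; its
   normalization to unit sum is the probability profile ``V_p``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .arg_graph import ArgGraph, ArgValidationError, classify_nodes

logger = logging.getLogger("argwalker")

__all__ = [
    "EdgeWeights",
    "TransitionMatrix",
    "RecombProfile",
    "backward_weights",
    "transition_matrix",
    "forward_walk",
    "walk_profile",
    "write_profile",
    "read_profile",
]


@dataclass(frozen=True)
class EdgeWeights:
    """Integer descendant-count weights per edge (exact arithmetic)."""

    w: dict[tuple[int, int], int]
    n: int

    def out_weight_sum(self, node: int) -> int:
        return sum(wt for (u, _), wt in self.w.items() if u == node)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic normalization of :class:`EdgeWeights`; leaves absorbing."""

    t: dict[tuple[int, int], float]


@dataclass(frozen=True)
class RecombProfile:
    """Per-haplotype recombination strengths for one hotspot.

    ``strengths`` maps haplotype id → accumulated leaf signal (V_L);
    ``probabilities`` is its normalization to unit sum (V_p).
    """

    strengths: dict[str, float]
    probabilities: dict[str, float]
    hotspot_id: str = "hotspot"

    @property
    def haplotype_ids(self) -> list[str]:
        return sorted(self.strengths)

    def values(self, which: str = "probabilities") -> np.ndarray:
        """Profile values in lexicographic haplotype-id order."""
        src = self.probabilities if which == "probabilities" else self.strengths
        return np.asarray([src[h] for h in self.haplotype_ids], dtype=float)


def _topological_order(g: ArgGraph) -> list[int]:
    # Kahn's algorithm on the validated DAG; deterministic (sorted frontier).
    succ: dict[int, list[int]] = {nid: [] for nid in g.node_ids}
    indeg = {nid: 0 for nid in g.node_ids}
    for u, v in g.edges:
        succ[u].append(v)
        indeg[v] += 1
    frontier = sorted(nid for nid in g.node_ids if indeg[nid] == 0)
    order: list[int] = []
    while frontier:
        node = frontier.pop()
        order.append(node)
        for child in succ[node]:
            indeg[child] -= 1
            if indeg[child] == 0:
                frontier.append(child)
        frontier.sort()
    if len(order) != g.n:
        raise ArgValidationError("cycle encountered in supposedly validated DAG")
    return order


def backward_weights(g: ArgGraph) -> EdgeWeights:
    """Assign descendant-count edge weights by a leaf-to-root sweep.

    Weights satisfy ``W(u→v) = 1 + Σ_{(v,w)∈E} W(v→w)`` exactly, in integer
    arithmetic, visiting nodes in reverse topological order (leaves first).
    ``W(u→v)`` equals one plus the number of nodes reachable from ``v``
    counted with path multiplicity, so descendant recombination nodes are
    double-counted — once per incoming path.
    """
    order = _topological_order(g)
    out_sum: dict[int, int] = {nid: 0 for nid in g.node_ids}  # Σ_w W(v→w)
    succ: dict[int, list[int]] = {nid: [] for nid in g.node_ids}
    for u, v in g.edges:
        succ[u].append(v)
    w: dict[tuple[int, int], int] = {}
    for node in reversed(order):
        total = 0
        for child in succ[node]:
            wt = 1 + out_sum[child]
            w[(node, child)] = wt
            total += wt
        out_sum[node] = total
    return EdgeWeights(w, g.n)


def transition_matrix(w: EdgeWeights) -> TransitionMatrix:
    """Row-normalize edge weights into transition probabilities."""
    row_sum: dict[int, int] = {}
    for (u, _), wt in w.w.items():
        if wt < 1:
            raise ArgValidationError(f"non-positive edge weight {wt}")
        row_sum[u] = row_sum.get(u, 0) + wt
    t = {(u, v): wt / row_sum[u] for (u, v), wt in w.w.items()}
    return TransitionMatrix(t)


def forward_walk(
    g: ArgGraph,
    t: TransitionMatrix,
    w: EdgeWeights,
    *,
    hotspot_id: str = "hotspot",
    tol: float = 1e-15,
) -> RecombProfile:
    """Propagate root signal down the ARG and collect it at labelled leaves.

    ``I`` is initialized on the roots with their outgoing weight sums, then
    ``I ← I·T`` / ``V_L ← V_L + I`` are iterated until every entry of ``I``
    is (numerically) zero; leaves are absorbing so this terminates within
    the longest root-to-leaf path length.  Entries of ``V_L`` not on
    labelled leaves are masked to zero; mass absorbed at unlabelled sinks is
    logged as lost mass.
    """
    if not g.leaf_labels:
        raise ArgValidationError("no labelled leaves: nothing to profile")
    if not g.edges:
        raise ArgValidationError("edgeless graph: total initial mass is zero")

    n = g.n
    cls = classify_nodes(g)
    rows, cols, vals = [], [], []
    for (u, v), p in t.t.items():
        rows.append(g.index_of(u))
        cols.append(g.index_of(v))
        vals.append(p)
    tmat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    # Root initialization from exact integer weight sums.  Weights can grow
    # like 2^(#recombination nodes); rescale the init by a power of two when
    # it would overflow double precision (V_p is invariant to this).
    init_ints = {root: 0 for root in cls.roots}
    for (u, _), wt in w.w.items():
        if u in init_ints:
            init_ints[u] += wt
    shift = max(0, max(init_ints.values(), default=0).bit_length() - 900)
    i_vec = np.zeros(n)
    for root, s_int in init_ints.items():
        i_vec[g.index_of(root)] = float(s_int >> shift) if shift else float(s_int)
    total_init = i_vec.sum()
    if total_init <= 0:
        raise ArgValidationError("total initial mass is zero")

    v_l = np.zeros(n)
    max_iter = n + 1  # longest path length + 1 is a (loose) upper bound
    for _ in range(max_iter):
        if i_vec.max(initial=0.0) <= tol:
            break
        i_vec = i_vec @ tmat
        v_l += i_vec

    labelled = sorted(g.leaf_labels)
    strengths = {g.leaf_labels[nid]: float(v_l[g.index_of(nid)]) for nid in labelled}
    lost = total_init - sum(strengths.values())
    if abs(lost) > 1e-9 * max(total_init, 1.0):
        logger.info(
            "hotspot %s: %.6g of %.6g signal mass absorbed at unlabelled sinks",
            hotspot_id, lost, total_init,
        )
    total = sum(strengths.values())
    if total <= 0:
        raise ArgValidationError("no signal mass reached any labelled leaf")
    probabilities = {h: s / total for h, s in strengths.items()}
    return RecombProfile(strengths, probabilities, hotspot_id)


def walk_profile(g: ArgGraph, hotspot_id: str = "hotspot") -> RecombProfile:
    """Full walker: backward weights → transition matrix → forward walk."""
    w = backward_weights(g)
    return forward_walk(g, transition_matrix(w), w, hotspot_id=hotspot_id)


# ---------------------------------------------------------------- file I/O


def write_profile(profile: RecombProfile, path) -> None:
    """Write ``hotspot_id<TAB>haplotype_id<TAB>V_L<TAB>V_p`` rows.

    Full double precision; rows ordered lexicographically by haplotype id so
    output is byte-stable.
    """
    with open(path, "w") as fh:
        fh.write("hotspot_id\thaplotype_id\tV_L\tV_p\n")
        for hap in profile.haplotype_ids:
            fh.write(
                f"{profile.hotspot_id}\t{hap}\t{profile.strengths[hap]!r}\t"
                f"{profile.probabilities[hap]!r}\n"
            )


def read_profile(path) -> RecombProfile:
    strengths: dict[str, float] = {}
    probabilities: dict[str, float] = {}
    hotspot_id = "hotspot"
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("hotspot_id\t"):
            raise ArgValidationError(f"{path}: not a profile TSV")
        for line in fh:
            hotspot_id, hap, vl, vp = line.rstrip("\n").split("\t")
            strengths[hap] = float(vl)
            probabilities[hap] = float(vp)
    return RecombProfile(strengths, probabilities, hotspot_id)
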
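"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the dip oracle
minimizes the sup-distance to a piecewise-linear unimodal CDF by linear
programming over every candidate mode placement; the walker oracle
enumerates root-to-leaf paths; the weight oracle counts reachable nodes
with path multiplicity by brute-force path enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def dip_oracle(values) -> float:
    """Exact dip statistic by LP over unimodal piecewise-linear CDFs.

    For each candidate mode (an atom at a distinct data value u_m) solve the
    LP minimizing d such that a nondecreasing CDF, convex left of the mode
    and concave right of it, with its only jump at the mode, stays within d
    of the empirical CDF everywhere.  Tied observations are collapsed to
    unique support points with multiplicities, so no off-mode jump can hide
    inside a tie stack.  A mode strictly between two data values need not
    be considered: the junction constraints are affine in the mode
    position, so any interior-mode solution can be slid to an adjacent
    support point without increasing d.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / n  # F(u_j); F(u_j^-) = cum[j-1] (0 before u_1)
    return min(_mode_lp(u, cum, m) for m in range(1, u.size + 1))


def _mode_lp(u: np.ndarray, cum: np.ndarray, m: int) -> float:
    # variables: g_1..g_m (left part at u_1..u_m), h_m..h_k (right part),
    # d; minimize d.  1-based indices follow the math; storage is 0-based.
    k = u.size
    nl, nr = m, k - m + 1
    nv = nl + nr + 1
    d_ix = nv - 1
    F = lambda j: cum[j - 1] if j >= 1 else 0.0  # noqa: E731

    A_ub, b_ub = [], []

    def band(var, target):  # |z_var - target| <= d
        row = np.zeros(nv)
        row[var], row[d_ix] = 1.0, -1.0
        A_ub.append(row.copy())
        b_ub.append(target)
        row[var] = -1.0
        A_ub.append(row)
        b_ub.append(-target)

    def le(lhs: dict, rhs=0.0):  # sum(coef*z) <= rhs
        row = np.zeros(nv)
        for var, coef in lhs.items():
            row[var] = coef
        A_ub.append(row)
        b_ub.append(rhs)

    # left part: G(u_j) = g_j for j < m, left limit G(u_m^-) = g_m
    for j in range(1, nl + 1):
        band(j - 1, F(j - 1))  # against F(u_j^-)
        if j < m:
            band(j - 1, F(j))  # against F(u_j)
    # right part: G(u_j) = h_j; left-limit constraint for j > m
    for i, j in enumerate(range(m, k + 1)):
        band(nl + i, F(j))
        if j > m:
            band(nl + i, F(j - 1))

    # monotonicity and the single jump at the mode
    for j in range(nl - 1):
        le({j: 1.0, j + 1: -1.0})
    for i in range(nr - 1):
        le({nl + i: 1.0, nl + i + 1: -1.0})
    le({nl - 1: 1.0, nl: -1.0})  # g_m <= h_m

    # nondecreasing slopes left of the mode, nonincreasing right of it
    for j in range(nl - 2):
        dx1, dx2 = u[j + 1] - u[j], u[j + 2] - u[j + 1]
        le({j: -dx2, j + 1: dx1 + dx2, j + 2: -dx1})
    for i in range(nr - 2):
        j = m - 1 + i  # 0-based into u
        dx1, dx2 = u[j + 1] - u[j], u[j + 2] - u[j + 1]
        le({nl + i: dx2, nl + i + 1: -(dx1 + dx2), nl + i + 2: dx1})

    res = linprog(
        c=np.eye(nv)[d_ix],
        A_ub=np.asarray(A_ub),
        b_ub=np.asarray(b_ub),
        bounds=[(0.0, 1.0)] * nv,
        method="highs",
    )
    return float(res.fun) if res.success else np.inf


def leaf_mass_oracle(edges, labels) -> dict[str, float]:
    """Leaf strengths by explicit root-to-leaf path enumeration.

    Recomputes edge weights by brute force (path-multiplicity reachable
    counts), normalizes them locally, and sums init(root) * prod(T) over
    every directed root-to-leaf path.
    """
    nodes = sorted({u for u, _ in edges} | {v for _, v in edges} | set(labels))
    succ = {nid: [] for nid in nodes}
    pred = {nid: [] for nid in nodes}
    for u, v in edges:
        succ[u].append(v)
        pred[v].append(u)

    def multiplicity_count(start) -> int:
        # number of nodes reachable from `start` counted once per distinct path
        total = 0
        stack = list(succ[start])
        while stack:
            node = stack.pop()
            total += 1
            stack.extend(succ[node])
        return total

    w = {(u, v): 1 + multiplicity_count(v) for u, v in edges}
    t = {}
    for u in nodes:
        s = sum(w[(u, v)] for v in succ[u])
        for v in succ[u]:
            t[(u, v)] = w[(u, v)] / s

    roots = [nid for nid in nodes if not pred[nid] and succ[nid]]
    mass = {lbl: 0.0 for lbl in labels.values()}

    def walk(node, amount):
        if not succ[node]:
            if node in labels:
                mass[labels[node]] += amount
            return
        for child in succ[node]:
            walk(child, amount * t[(node, child)])

    for root in roots:
        init = sum(w[(root, v)] for v in succ[root])
        walk(root, float(init))
    return mass


def weight_oracle(edges) -> dict[tuple[int, int], int]:
    """Edge weights as 1 + brute-force path-multiplicity reachable count."""
    nodes = sorted({u for u, _ in edges} | {v for _, v in edges})
    succ = {nid: [] for nid in nodes}
    for u, v in edges:
        succ[u].append(v)

    def count(start) -> int:
        total = 0
        stack = list(succ[start])
        while stack:
            node = stack.pop()
            total += 1
            stack.extend(succ[node])
        return total

    return {(u, v): 1 + count(v) for u, v in edges}


def best_two_means_split(values) -> int:
    """Index k minimizing within-cluster SSE over all 2-partitions of sorted values."""
    v = np.sort(np.asarray(values, dtype=float))
    best_k, best_cost = 1, np.inf
    for k in range(1, v.size):
        cost = ((v[:k] - v[:k].mean()) ** 2).sum() + ((v[k:] - v[k:].mean()) ** 2).sum()
        if cost < best_cost - 1e-15:
            best_cost, best_k = cost, k
    return best_k


def auc_by_pair_counting(scores, labels) -> float:
    """AUC as the tie-corrected fraction of concordant (positive, negative) pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = conc = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1
        if p > q:
            conc += 1
        elif p == q:
            conc += 0.5
    return conc / total
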
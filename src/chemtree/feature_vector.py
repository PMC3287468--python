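"""Path-frequency feature vectors of level K.

The feature vector ``f_K(T)`` of a labeled multitree counts, for every label
sequence ``t`` with at most ``K + 1`` labels, the directed simple paths whose
vertex labels spell ``t``.  Parallel edges are collapsed before counting, so
bond multiplicity never affects the vector; a path and its reverse are counted
separately, hence ``#t = #reverse(t)`` for every realized vector.  Level 0 is
the molecular formula (one entry per label).
"""

from __future__ import annotations

from typing import Mapping

from .chem_model import Alphabet, InstanceError, MultiTreeSolution

__all__ = [
    "FeatureVector",
    "count_paths",
    "leq",
    "widen",
    "multiplicity_budget",
]


class FeatureVector(dict):
    """Counts of directed label-sequence paths; missing entries are 0.

    A thin ``dict`` subclass keyed by label tuples, carrying the level ``K``.
    """

    def __init__(self, K: int, counts: Mapping[tuple[str, ...], int] | None = None):
        if K < 0:
            raise InstanceError("level K must be non-negative")
        super().__init__(counts or {})
        self.K = K

    def __missing__(self, key):  # absent sequence => count 0
        return 0


def count_paths(tree: MultiTreeSolution, K: int) -> FeatureVector:
    """Compute ``f_K`` of a multitree by depth-bounded DFS from every vertex.

    In a tree every ordered vertex pair is joined by exactly one simple path,
    so enumerating, from each start vertex, all paths of at most ``K`` edges
    that never revisit a vertex yields each directed path exactly once.
    """
    if K < 0:
        raise InstanceError("level K must be non-negative")
    fv = FeatureVector(K)
    adj = tree.adjacency()
    labels = tree.vertices
    for start in range(tree.n):
        seq = [labels[start]]
        fv[tuple(seq)] = fv[tuple(seq)] + 1

        def walk(v: int, prev: int, edges_left: int) -> None:
            if edges_left == 0:
                return
            for w in adj[v]:
                if w == prev:
                    continue
                seq.append(labels[w])
                t = tuple(seq)
                fv[t] = fv[t] + 1
                walk(w, v, edges_left - 1)
                seq.pop()

        walk(start, -1, K)
    return fv


def leq(a: FeatureVector, b: FeatureVector) -> bool:
    """Entrywise ``a <= b`` (absent entries count as 0)."""
    if a.K != b.K:
        raise InstanceError("cannot compare feature vectors of different levels")
    return all(a[t] <= b.get(t, 0) for t in a)


def widen(g: FeatureVector, w: int) -> tuple[FeatureVector, FeatureVector]:
    """Turn a realized feature vector into the bound pair of width ``w``.

    Every entry ``a > 0`` with two or more labels becomes ``[max(0, a - w),
    a + w]``; entries that are 0 stay 0 in both bounds (the instance built
    from the result is closed-world: unseen sequences are forbidden); length-1
    entries (atom counts) are copied unchanged into both bounds so that the
    standing assumption ``g_L(l) = g_U(l)`` keeps holding.  With ``w = 0`` the
    box degenerates to the single-vector (exact path frequency) problem.
    """
    if w < 0:
        raise InstanceError("width w must be non-negative")
    g_l, g_u = FeatureVector(g.K), FeatureVector(g.K)
    for seq, a in g.items():
        if a <= 0:
            continue
        if len(seq) == 1:
            g_l[seq] = g_u[seq] = a
        else:
            g_l[seq] = max(0, a - w)
            g_u[seq] = a + w
    return g_l, g_u


def multiplicity_budget(counts: Mapping[str, int], alphabet: Alphabet) -> int:
    """Extra bond units available for multiple bonds: ``M = e_m - e_s``.

    With atom counts fixed, the degree-sum formula gives the multiplicity-
    counted edge number ``e_m = sum(val(l) * g(l)) / 2`` while the tree
    condition fixes the simple edge number ``e_s = n - 1``; their difference
    is the exact total of ``m_e - 1`` over the edges of any solution.
    """
    deg_sum = sum(alphabet.val(lab) * c for lab, c in counts.items())
    n = sum(counts.values())
    if deg_sum % 2:
        raise InstanceError("odd total valence sum")
    m = deg_sum // 2 - (n - 1)
    if m < 0:
        raise InstanceError("negative multiplicity budget: instance infeasible")
    return m
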
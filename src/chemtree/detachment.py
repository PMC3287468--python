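"""Connected loopless detachments and the detachment-cut.

An ``r``-detachment of a multigraph ``G`` splits every vertex ``v`` into
``r(v)`` copies and reroutes each edge to one copy of each endpoint; a degree
specification ``rho`` prescribes the degree of every copy.  Chemical reading:
contract all atoms sharing a label into one vertex -- recovering the molecule
from the contraction is exactly finding a connected, loopless detachment whose
copy degrees are the valences.

:func:`detachment_feasible` decides existence of a connected loopless
rho-detachment through a family of subset/degree conditions checked
exhaustively over the (small) label set; :func:`brute_force_detachment` is the
independent oracle that searches for an explicit witness.  The enumeration
uses the same machinery as a pruning test: the not-yet-placed vertices of each
label are aggregated into one vertex per label, the open rightmost path into
one extra vertex, and edge capacities come from the upper bound vector's pair
entries minus the bonds already present -- if no connected loopless detachment
can exist even in this relaxation, the current state is dead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

from .branching import SearchTree
from .chem_model import Instance

__all__ = [
    "DetachmentProblem",
    "RemainderVectors",
    "detachment_feasible",
    "brute_force_detachment",
    "subset_condition",
    "build_cut_problems",
    "detachment_cut",
]


@dataclass
class DetachmentProblem:
    """A multigraph with split counts and (optionally) a degree specification.

    ``edges`` maps vertex pairs ``(u, v)`` with ``u <= v`` to multiplicities;
    ``u == v`` is a self-loop (counting 2 toward the degree of ``u``).
    """

    n: int
    edges: dict[tuple[int, int], int]
    r: Sequence[int]
    rho: Optional[Sequence[Sequence[int]]] = None

    def degree(self, v: int) -> int:
        d = 0
        for (a, b), m in self.edges.items():
            if a == v:
                d += m
            if b == v:
                d += m
        return d

    def loops(self, v: int) -> int:
        return self.edges.get((v, v), 0)

    def to_edgelist(self) -> str:
        """Plain-text edge list (``u v mult`` per line) for debugging dumps."""
        head = " ".join(f"{v}:{self.r[v]}" for v in range(self.n))
        lines = [f"# vertices r = {head}"]
        for (a, b), m in sorted(self.edges.items()):
            lines.append(f"{a} {b} {m}")
        return "\n".join(lines) + "\n"

    def validate(self) -> None:
        if len(self.r) != self.n or any(rv < 1 for rv in self.r):
            raise ValueError("r must assign a positive split count to every vertex")
        if self.rho is not None:
            if len(self.rho) != self.n:
                raise ValueError("rho must cover every vertex")
            for v in range(self.n):
                if len(self.rho[v]) != self.r[v]:
                    raise ValueError(f"rho({v}) must have r({v}) entries")
                if sum(self.rho[v]) != self.degree(v):
                    raise ValueError(
                        f"sum of rho({v}) must equal deg({v}) (loops count twice)"
                    )


def _components_without(P: DetachmentProblem, removed: frozenset[int]) -> int:
    """Components of the induced multigraph on the kept vertices (loops moot)."""
    kept = [v for v in range(P.n) if v not in removed]
    if not kept:
        return 0
    adj: dict[int, set[int]] = {v: set() for v in kept}
    for (a, b), m in P.edges.items():
        if m > 0 and a != b and a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    seen: set[int] = set()
    comps = 0
    for v in kept:
        if v in seen:
            continue
        comps += 1
        stack = [v]
        seen.add(v)
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
    return comps


def subset_condition(P: DetachmentProblem) -> bool:
    """The subset test: ``r(X) + c(G - X) - d(X, V; G) <= 1`` for all X != {}.

    ``d(X, V; G)`` counts every edge with at least one endpoint in ``X`` once
    per unit of multiplicity (a self-loop counts once).  Checked exhaustively
    over the ``2^n - 1`` nonempty subsets.
    """
    verts = list(range(P.n))
    for k in range(1, P.n + 1):
        for X in combinations(verts, k):
            Xs = frozenset(X)
            rX = sum(P.r[v] for v in X)
            d = sum(
                m for (a, b), m in P.edges.items() if a in Xs or b in Xs
            )
            if rX + _components_without(P, Xs) - d > 1:
                return False
    return True


def detachment_feasible(P: DetachmentProblem) -> bool:
    """Decide whether ``P`` admits a connected loopless rho-detachment.

    Conditions: every copy has prescribed degree at least 1 (an isolated copy
    disconnects anything with two or more copies overall); the self-loops at
    each vertex can be spread over pairwise-distinct copies within the degree
    prescription (``sum_j min(rho_j(v), loops(v)) >= 2 loops(v)``); the
    loop-free skeleton of ``G`` is connected; and the subset condition holds.
    Matches the explicit-witness search of :func:`brute_force_detachment` on
    every problem small enough to sweep.
    """
    P.validate()
    if P.rho is None:
        raise ValueError("detachment_feasible requires a degree specification")
    total_copies = sum(P.r)
    if total_copies == 1:
        return not P.edges  # one copy: connected iff trivially, loopless iff no loop
    for v in range(P.n):
        if any(x < 1 for x in P.rho[v]):
            return False
        L = P.loops(v)
        if L and sum(min(x, L) for x in P.rho[v]) < 2 * L:
            return False
    if P.n > 1 and _components_without(P, frozenset()) != 1:
        return False
    return subset_condition(P)


def brute_force_detachment(
    P: DetachmentProblem, max_copies: int = 8, max_units: int = 10
) -> bool:
    """Search for an explicit connected loopless detachment (test oracle).

    Expands multiplicities into unit edges and assigns every unit to a pair of
    copies, respecting the degree prescription exactly; self-loop units must
    join two distinct copies of their vertex.  Exponential; guarded by caps.
    """
    P.validate()
    if P.rho is None:
        raise ValueError("brute_force_detachment requires a degree specification")
    if sum(P.r) > max_copies:
        raise ValueError("split size exceeds brute-force cap")
    units: list[tuple[int, int]] = []
    for (a, b), m in sorted(P.edges.items()):
        units.extend([(a, b)] * m)
    if len(units) > max_units:
        raise ValueError("edge count exceeds brute-force cap")

    offset = [0] * P.n  # copy index space: global ids
    tot = 0
    for v in range(P.n):
        offset[v] = tot
        tot += P.r[v]
    rem = [P.rho[v][i] for v in range(P.n) for i in range(P.r[v])]
    chosen: list[tuple[int, int]] = []

    def connected() -> bool:
        adj: list[list[int]] = [[] for _ in range(tot)]
        for x, y in chosen:
            adj[x].append(y)
            adj[y].append(x)
        seen = {0}
        stack = [0]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == tot

    def place(k: int, prev_same: tuple[int, int]) -> bool:
        if k == len(units):
            return all(x == 0 for x in rem) and connected()
        a, b = units[k]
        same_as_prev = k > 0 and units[k - 1] == units[k]
        if a == b:
            pairs = [
                (offset[a] + i, offset[a] + j)
                for i, j in combinations(range(P.r[a]), 2)
            ]
        else:
            pairs = [
                (offset[a] + i, offset[b] + j)
                for i in range(P.r[a])
                for j in range(P.r[b])
            ]
        for x, y in pairs:
            if same_as_prev and (x, y) < prev_same:
                continue  # identical units: assign in non-decreasing order
            if rem[x] < 1 or rem[y] < 1:
                continue
            rem[x] -= 1
            rem[y] -= 1
            chosen.append((x, y))
            if place(k + 1, (x, y)):
                return True
            chosen.pop()
            rem[x] += 1
            rem[y] += 1
        return False

    return place(0, (-1, -1))


# ----------------------------------------------------------------- the cut
@dataclass
class RemainderVectors:
    """Level-1 pair allowances still available given the current tree.

    ``g_hat_u`` / ``g_hat_l`` map unordered label-index pairs ``(i, j)`` with
    ``i <= j`` to the number of further bonds allowed / still demanded between
    those labels; ``rp_label_counts[i]`` is the number of open rightmost-path
    vertices with label i, ``h`` the rightmost-path length minus one.
    """

    g_hat_u: dict[tuple[int, int], float]
    g_hat_l: dict[tuple[int, int], int]
    rp_label_counts: list[int]
    h: int


def _pair_bound(inst_value: float, diagonal: bool, lower: bool) -> float:
    """Convert a directed length-2 sequence bound into an undirected bond bound."""
    if math.isinf(inst_value):
        return math.inf
    if not diagonal:
        return inst_value
    # #(l,l) counts both traversals of every l-l bond
    return math.ceil(inst_value / 2) if lower else inst_value // 2


def build_cut_problems(
    T: SearchTree, inst: Instance
) -> tuple[RemainderVectors, Optional[DetachmentProblem]]:
    """Aggregate the future of a search state into a detachment problem.

    Vertices of the relaxation: one per label that still has unplaced atoms
    (split count = how many), plus one vertex standing for the whole open
    rightmost path (split count 1).  Edge capacities are the upper pair
    allowances left after subtracting the bonds already present; capacities to
    the rightmost-path vertex are additionally capped by the path's residual
    valence.  All caps err on the generous side: the test may fail to prune
    but can never prune a completable state.
    """
    a = inst.alphabet
    s = a.size
    labs = [a.labels[i] for i in range(s)]
    # bonds already present in T, by unordered label pair
    bonds: dict[tuple[int, int], int] = {}
    for v in range(len(T)):
        p = T.parent[v]
        if p < 0:
            continue
        key = tuple(sorted((T.label[v], T.label[p])))
        bonds[key] = bonds.get(key, 0) + 1
    g_hat_u: dict[tuple[int, int], float] = {}
    g_hat_l: dict[tuple[int, int], int] = {}
    for i in range(s):
        for j in range(i, s):
            seq = (labs[i], labs[j])
            have = bonds.get((i, j), 0)
            up = _pair_bound(inst.upper(seq), i == j, lower=False)
            lo = _pair_bound(inst.lower(seq), i == j, lower=True)
            u_left = math.inf if math.isinf(up) else max(0, up - have)
            g_hat_u[(i, j)] = u_left
            g_hat_l[(i, j)] = max(0, int(lo) - have)

    # open rightmost-path vertices and their residual valence
    rp_label_counts = [0] * s
    residual = 0
    k = len(T.rp) - 1
    for j, v in enumerate(T.rp):
        opens = (1 if j < k else 0) + (1 if T.parent[v] >= 0 else 0)
        free = T.vals[T.label[v]] - T.used[v] - opens
        if free > 0:
            rp_label_counts[T.label[v]] += 1
            residual += free

    active = [i for i in range(s) if T.remaining[i] > 0]
    if not active:
        return (
            RemainderVectors(g_hat_u, g_hat_l, rp_label_counts, k),
            None,
        )
    idx = {lab: pos for pos, lab in enumerate(active)}
    n_dp = len(active) + 1
    rp_vertex = len(active)
    big = sum(T.vals[i] * T.remaining[i] for i in range(s)) + residual + 1
    edges: dict[tuple[int, int], int] = {}
    for pos, i in enumerate(active):
        for pos2 in range(pos, len(active)):
            j = active[pos2]
            cap = g_hat_u[(min(i, j), max(i, j))]
            cap = big if math.isinf(cap) else int(cap)
            if cap > 0:
                edges[(pos, pos2)] = min(cap, big)
        # capacity toward the open rightmost path
        cap_rp = 0
        for j in range(s):
            if rp_label_counts[j] == 0:
                continue
            allow = g_hat_u[(min(i, j), max(i, j))]
            cap_rp = big if math.isinf(allow) else cap_rp + int(allow)
            if cap_rp >= big:
                cap_rp = big
                break
        cap_rp = min(cap_rp, residual)
        if cap_rp > 0:
            edges[(pos, rp_vertex)] = cap_rp
    r = [T.remaining[i] for i in active] + [1]
    problem = DetachmentProblem(n_dp, edges, r)
    return RemainderVectors(g_hat_u, g_hat_l, rp_label_counts, k), problem


def detachment_cut(T: SearchTree, inst: Instance) -> bool:
    """Keep (True) unless no completion can exist.

    (a) every remaining bond demand of the lower vector must fit into the
    ``n - |T|`` bonds a completion can still create; (b) the aggregated upper
    relaxation must pass the detachment subset condition.
    """
    if len(T) == 0 or len(T) >= inst.n:
        return True
    rv, problem = build_cut_problems(T, inst)
    demand = sum(rv.g_hat_l.values())
    if demand > inst.n - len(T):
        return False
    if problem is not None and not subset_condition(problem):
        return False
    return True
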
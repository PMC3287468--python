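"""Search-tree states and the leaf-appending branching operation.

The enumeration walks a family tree of left-heavy rooted trees: every state is
obtained from its parent by appending one labeled leaf to a vertex of the
rightmost path, and conversely removing the rightmost leaf of a left-heavy
tree yields its (still left-heavy) parent state.  Whenever an append happens
at position ``i`` of the rightmost path, the deeper vertices ``r_{i+1}..r_k``
leave the path for good; the valence constraint then forces the multiplicity
of each of their parent edges (valence minus multiplicities of already-closed
child edges), which is applied deepest-first and may reveal infeasibility.
Edges still on the rightmost path stay "open" and carry no multiplicity yet.

:class:`SearchTree` is a mutable state with cheap apply/undo so the driver can
do depth-first search without copying; :func:`children` exposes the spec-level
set contract (all valid one-leaf extensions as independent states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .chem_model import Instance, MultiTreeSolution

__all__ = ["SearchTree", "Undo", "children", "close_vertices", "finalize"]


@dataclass
class Undo:
    """Reversal record of one extension; interpreted by :meth:`SearchTree.undo`."""

    kind: str  # "root" | "leaf"
    vertex: int
    position: int = -1
    closed: list[int] = field(default_factory=list)  # vertices whose edge got closed
    old_rp_tail: list[int] = field(default_factory=list)
    changed: list[tuple[int, ...]] = field(default_factory=list)  # touched f entries
    fail: Optional[str] = None  # set when the extension was structurally impossible


class SearchTree:
    """A partially built left-heavy rooted multitree for one instance."""

    def __init__(self, inst: Instance):
        self.inst = inst
        a = inst.alphabet
        self.s = a.size
        self.vals = [a.valence[l] for l in a.labels]
        # per-vertex arrays
        self.label: list[int] = []
        self.parent: list[int] = []
        self.depth: list[int] = []
        self.children: list[list[int]] = []
        self.mult: list[Optional[int]] = []  # multiplicity of edge to parent
        self.used: list[int] = []  # closed multiplicity incident to vertex
        self.size: list[int] = []  # subtree size within the growing component
        self.rp: list[int] = []  # rightmost path of the growing component
        self.remaining: list[int] = [inst.count(l) for l in a.labels]
        self.f: dict[tuple[int, ...], int] = {}  # feature counts, index-keyed
        self.m_running = 0  # sum of (mult - 1) over closed edges
        self.sub_root = 0  # root of the growing component (phase 2: 2nd half root)
        # index-keyed bound lookups
        self._upper: dict[tuple[int, ...], float] = {
            tuple(a.index(l) for l in seq): u for seq, u in inst.g_u.items()
        }
        self._upper_default = inst.upper_default
        self.lower_entries: list[tuple[tuple[int, ...], int]] = [
            (tuple(a.index(l) for l in seq), lo)
            for seq, lo in inst.g_l.items()
            if lo > 0
        ]

    # ------------------------------------------------------------------ basics
    def __len__(self) -> int:
        return len(self.label)

    def upper(self, t: tuple[int, ...]) -> float:
        u = self._upper.get(t)
        if u is not None:
            return u
        return 0 if len(t) == 1 else self._upper_default

    def neighbors(self, v: int) -> Iterator[int]:
        p = self.parent[v]
        if p >= 0:
            yield p
        yield from self.children[v]

    # ------------------------------------------------------- sequence machinery
    def pair_key(self, depth: int, lab: int) -> tuple[int, int]:
        return (depth, self.s - lab)

    def subtree_keys(self, v: int):
        """Depth-label pair keys of the subtree at ``v`` (left-heavy order)."""
        base = self.depth[v]
        stack = [v]
        while stack:
            u = stack.pop()
            yield (self.depth[u] - base, self.s - self.label[u])
            for c in reversed(self.children[u]):
                stack.append(c)

    def _seq_geq(self, a: int, b: int) -> bool:
        ita, itb = self.subtree_keys(a), self.subtree_keys(b)
        for ka, kb in zip(ita, itb):
            if ka != kb:
                return ka > kb
        return next(itb, None) is None

    def _left_heavy_along_path(self, i: int) -> bool:
        """Re-check sibling order at the ancestors whose subtree just grew."""
        for j in range(i + 1):
            a = self.rp[j]
            ch = self.children[a]
            if len(ch) >= 2 and not self._seq_geq(ch[-2], ch[-1]):
                return False
        return True

    def dls_keys(self, root: int) -> tuple[tuple[int, int], ...]:
        return tuple(self.subtree_keys(root))

    # ------------------------------------------------------------- feature work
    def _add_vertex_paths(self, u: int, undo: Undo, check: bool = True) -> bool:
        """Count the new directed paths with endpoint ``u``; False on an upper hit.

        Appending a leaf creates exactly the simple paths having ``u`` as an
        endpoint; each contributes one path in either direction.  Only the
        touched entries need re-checking against the upper bound; with
        ``check=False`` the counts are maintained but never tested (the
        feature-vector-cut is disabled).
        """
        f, K = self.f, self.inst.K

        def bump(t: tuple[int, ...]) -> bool:
            f[t] = f.get(t, 0) + 1
            undo.changed.append(t)
            return (not check) or f[t] <= self.upper(t)

        t0 = (self.label[u],)
        if not bump(t0):
            return False
        if K == 0:
            return True
        seq = [self.label[u]]

        def walk(v: int, prev: int, edges_left: int) -> bool:
            for w in self.neighbors(v):
                if w == prev or w == u:
                    continue
                seq.append(self.label[w])
                tf = tuple(seq)
                good = bump(tf) and bump(tf[::-1])
                if good and edges_left > 1:
                    good = walk(w, v, edges_left - 1)
                seq.pop()
                if not good:
                    return False
            return True

        return walk(u, -1, K)

    # --------------------------------------------------------------- extension
    def extend_root(self, lab: int, check_upper: bool = True) -> Optional[Undo]:
        """Start the growing component with a single vertex of label ``lab``."""
        assert not self.rp, "component already started"
        if self.remaining[lab] <= 0:
            return None
        undo = Undo("root", len(self.label))
        v = len(self.label)
        self.label.append(lab)
        self.parent.append(-1)
        self.depth.append(0)
        self.children.append([])
        self.mult.append(None)
        self.used.append(0)
        self.size.append(1)
        self.rp = [v]
        self.sub_root = v
        self.remaining[lab] -= 1
        if not self._add_vertex_paths(v, undo, check_upper):
            undo.fail = "feature"
            self.undo(undo)
        return undo

    def extend_bridge_root(self, lab: int, check_upper: bool = True) -> Optional[Undo]:
        """Start the second half of a bicentroid solution across the bridge.

        The first half (vertices ``0..n/2-1``) must be fully closed except for
        the root's residual valence, which the open bridge edge will carry.
        The new vertex becomes the growing component's root at depth 0; path
        counting still sees the bridge, so cross-bridge paths are tracked.
        """
        if self.remaining[lab] <= 0:
            return None
        undo = Undo("bridge_root", len(self.label), old_rp_tail=self.rp)
        u = len(self.label)
        self.label.append(lab)
        self.parent.append(0)
        self.depth.append(0)
        self.children.append([])
        self.children[0].append(u)
        self.mult.append(None)
        self.used.append(0)
        self.size.append(1)
        self.rp = [u]
        self.sub_root = u
        self.remaining[lab] -= 1
        if not self._add_vertex_paths(u, undo, check_upper):
            undo.fail = "feature"
            self.undo(undo)
        return undo

    def extend(self, i: int, lab: int, check_upper: bool = True) -> Optional[Undo]:
        """Append a leaf with label ``lab`` at rightmost-path position ``i``.

        Returns an :class:`Undo` on success.  Returns ``None`` (state
        untouched) for structurally impossible extensions; returns an Undo
        with ``fail`` set when the append succeeded structurally but a forced
        closing or the incremental upper-bound check failed (the caller counts
        the prune and undoes).
        """
        if self.remaining[lab] <= 0:
            return None
        r_i = self.rp[i]
        undo = Undo("leaf", len(self.label), position=i, old_rp_tail=self.rp[i + 1 :])
        # close the vertices leaving the rightmost path, deepest first
        for j in range(len(self.rp) - 1, i, -1):
            v = self.rp[j]
            m = self.vals[self.label[v]] - self.used[v]
            if m < 1:
                undo.fail = "valence"
                self.undo(undo)
                return undo
            self.mult[v] = m
            self.used[v] += m
            self.used[self.parent[v]] += m
            self.m_running += m - 1
            undo.closed.append(v)
        # the attach vertex keeps one open edge per remaining endpoint
        opens = 1 + (1 if self.parent[r_i] >= 0 else 0)
        if self.used[r_i] + opens > self.vals[self.label[r_i]]:
            undo.fail = "valence"
            self.undo(undo)
            return undo
        u = len(self.label)
        self.label.append(lab)
        self.parent.append(r_i)
        self.depth.append(self.depth[r_i] + 1)
        self.children.append([])
        self.children[r_i].append(u)
        self.mult.append(None)
        self.used.append(0)
        self.size.append(1)
        del self.rp[i + 1 :]
        self.rp.append(u)
        self.remaining[lab] -= 1
        for j in range(i + 1):
            self.size[self.rp[j]] += 1
        if not self._left_heavy_along_path(i):
            undo.fail = "leftheavy"
            self.undo(undo)
            return undo
        if not self._add_vertex_paths(u, undo, check_upper):
            undo.fail = "feature"
            self.undo(undo)
            return undo
        return undo

    def undo(self, undo: Undo) -> None:
        for t in reversed(undo.changed):
            self.f[t] -= 1
            if self.f[t] == 0:
                del self.f[t]
        undo.changed.clear()
        if undo.kind == "root":
            if len(self.label) > undo.vertex:  # vertex was actually added
                self.remaining[self.label[undo.vertex]] += 1
                self._pop_vertex()
                self.rp = []
            return
        if undo.kind == "bridge_root":
            if len(self.label) > undo.vertex:
                self.remaining[self.label[undo.vertex]] += 1
                self.children[0].remove(undo.vertex)
                self._pop_vertex()
            self.rp = undo.old_rp_tail
            self.sub_root = 0
            return
        u = undo.vertex
        if len(self.label) > u:  # leaf was actually added
            r_i = self.parent[u]
            self.remaining[self.label[u]] += 1
            self.children[r_i].remove(u)
            for j in range(undo.position + 1):
                self.size[self.rp[j]] -= 1
            self._pop_vertex()
            del self.rp[undo.position + 1 :]
        for v in reversed(undo.closed):
            m = self.mult[v]
            self.mult[v] = None
            self.used[v] -= m
            self.used[self.parent[v]] -= m
            self.m_running -= m - 1
        undo.closed.clear()
        self.rp[undo.position + 1 :] = undo.old_rp_tail

    def _pop_vertex(self) -> None:
        for arr in (
            self.label,
            self.parent,
            self.depth,
            self.children,
            self.mult,
            self.used,
            self.size,
        ):
            arr.pop()

    # -------------------------------------------------------------- completion
    def closing_plan(self) -> Optional[tuple[list[tuple[int, int]], int]]:
        """Forced multiplicities of the still-open rightmost-path edges.

        Returns ``(plan, residual)`` where ``plan`` lists ``(vertex, mult)``
        deepest-first for every non-root vertex of the rightmost path and
        ``residual`` is the valence left at the component root afterwards, or
        ``None`` if some forced multiplicity would drop below 1.  The state is
        not modified.
        """
        plan: list[tuple[int, int]] = []
        carry = 0
        for j in range(len(self.rp) - 1, 0, -1):
            v = self.rp[j]
            m = self.vals[self.label[v]] - self.used[v] - carry
            if m < 1:
                return None
            plan.append((v, m))
            carry = m
        root = self.rp[0]
        residual = self.vals[self.label[root]] - self.used[root] - carry
        if residual < 0:
            return None
        return plan, residual

    def apply_closing(self, plan: list[tuple[int, int]]) -> None:
        for v, m in plan:
            self.mult[v] = m
            self.used[v] += m
            self.used[self.parent[v]] += m
            self.m_running += m - 1

    def revert_closing(self, plan: list[tuple[int, int]]) -> None:
        for v, m in reversed(plan):
            self.mult[v] = None
            self.used[v] -= m
            self.used[self.parent[v]] -= m
            self.m_running -= m - 1

    def lower_ok(self) -> bool:
        """Condition checked only at full size: every lower bound is met."""
        return all(self.f.get(t, 0) >= lo for t, lo in self.lower_entries)

    def upper_ok(self) -> bool:
        """Full upper-bound check; incremental search keeps this true, but a
        completed tree must satisfy it even with the feature cut disabled."""
        return all(c <= self.upper(t) for t, c in self.f.items())

    def to_solution(
        self, extra_edges: list[tuple[int, int, int]] = ()
    ) -> MultiTreeSolution:
        labels = tuple(self.inst.alphabet.labels[l] for l in self.label)
        edges = [
            (min(v, self.parent[v]), max(v, self.parent[v]), self.mult[v])
            for v in range(len(self.label))
            if self.parent[v] >= 0 and self.mult[v] is not None
        ]
        edges.extend(extra_edges)
        return MultiTreeSolution(labels, tuple(sorted(edges)))

    def clone(self) -> "SearchTree":
        c = SearchTree.__new__(SearchTree)
        c.inst, c.s, c.vals = self.inst, self.s, self.vals
        c.label = list(self.label)
        c.parent = list(self.parent)
        c.depth = list(self.depth)
        c.children = [list(x) for x in self.children]
        c.mult = list(self.mult)
        c.used = list(self.used)
        c.size = list(self.size)
        c.rp = list(self.rp)
        c.remaining = list(self.remaining)
        c.f = dict(self.f)
        c.m_running = self.m_running
        c.sub_root = self.sub_root
        c._upper = self._upper
        c._upper_default = self._upper_default
        c.lower_entries = self.lower_entries
        return c


# ----------------------------------------------------------- spec-level surface
def children(T: SearchTree, inst: Instance) -> list[SearchTree]:
    """All valid one-leaf extensions of ``T`` as independent states.

    For the empty state this is one single-vertex tree per label with budget
    left; otherwise one state per (rightmost-path position, label) pair whose
    extension stays left-heavy and valence-feasible.  Bound-based pruning is
    deliberately not applied here: this is the raw branching set.
    """
    out: list[SearchTree] = []
    if len(T) == 0:
        for lab in range(inst.alphabet.size):
            c = T.clone()
            rec = c.extend_root(lab, check_upper=False)
            if rec is not None and rec.fail is None:
                out.append(c)
        return out
    if len(T) >= inst.n:
        return out
    for i in range(len(T.rp)):
        for lab in range(inst.alphabet.size):
            c = T.clone()
            rec = c.extend(i, lab, check_upper=False)
            if rec is not None and rec.fail is None:
                out.append(c)
    return out


def close_vertices(T: SearchTree, i: int) -> bool:
    """Close rightmost-path vertices below position ``i`` in place.

    Returns ``False`` (state untouched) when a forced multiplicity would be
    infeasible -- the prune signal.
    """
    plan: list[tuple[int, int]] = []
    carry = 0
    for j in range(len(T.rp) - 1, i, -1):
        v = T.rp[j]
        m = T.vals[T.label[v]] - T.used[v] - carry
        if m < 1:
            return False
        plan.append((v, m))
        carry = m
    T.apply_closing(plan)
    del T.rp[i + 1 :]
    return True


def finalize(T: SearchTree, inst: Instance) -> Optional[MultiTreeSolution]:
    """Complete a full-size state into a solution, or signal a prune.

    Closes the remaining rightmost-path edges, requires the root's degree to
    hit its valence exactly, and checks the lower feature-vector condition.
    The state is left unmodified.
    """
    if len(T) != inst.n:
        raise ValueError("finalize requires a full-size tree")
    res = T.closing_plan()
    if res is None:
        return None
    plan, residual = res
    if residual != 0:
        return None
    if not (T.lower_ok() and T.upper_ok()):
        return None
    T.apply_closing(plan)
    try:
        sol = T.to_solution()
    finally:
        T.revert_closing(plan)
    return sol
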
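"""Canonical forms for labeled (multi)trees.

A rooted ordered tree is represented canonically by its depth-label sequence:
the DFS-ordered list of ``(depth, label)`` pairs.  Pairs are ordered with
depth dominating (deeper is larger) and, at equal depth, by the alphabet's
declared label order (earlier label is larger); sequences compare
lexicographically with a strict prefix smaller.  The embedding whose sequence
is maximal over all plane embeddings is the left-heavy embedding, the unique
representative of a rooted tree's isomorphism class.

Free trees are rooted at their centroid (Jordan): either the unique vertex
whose removal leaves components of at most ``floor((n-1)/2)`` vertices, or the
unique edge splitting the tree into two halves of ``n/2`` vertices each.
Combining both gives :func:`canonical_key`, a total key that is equal for two
multitrees exactly when they are isomorphic as labeled multigraphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .chem_model import Alphabet, MultiTreeSolution

__all__ = [
    "RootedTree",
    "DepthLabelSequence",
    "Centroid",
    "depth_label_sequence",
    "compare_sequences",
    "is_left_heavy",
    "find_centroid",
    "canonical_key",
    "key_string",
]


@dataclass
class RootedTree:
    """A rooted *ordered* tree: per-vertex labels and ordered child lists."""

    labels: Sequence[str]
    children: Sequence[Sequence[int]]
    root: int = 0

    @classmethod
    def from_parents(
        cls, labels: Sequence[str], parents: Sequence[int], root: int = 0
    ) -> "RootedTree":
        ch: list[list[int]] = [[] for _ in labels]
        for v, p in enumerate(parents):
            if p >= 0:
                ch[p].append(v)
        return cls(labels, ch, root)


@dataclass(frozen=True)
class DepthLabelSequence:
    """DFS-ordered ``(depth, label)`` pairs of a plane tree."""

    items: tuple[tuple[int, str], ...]

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class Centroid:
    kind: Literal["unicentroid", "bicentroid"]
    vertices: tuple[int, ...]  # (v*,) or the edge (u, v)


def _pair_key(depth: int, label: str, alphabet: Alphabet) -> tuple[int, int]:
    # deeper pair is larger; at equal depth, earlier alphabet label is larger
    return (depth, alphabet.size - alphabet.index(label))


def depth_label_sequence(tree: RootedTree) -> DepthLabelSequence:
    items: list[tuple[int, str]] = []
    stack: list[tuple[int, int]] = [(tree.root, 0)]
    while stack:
        v, d = stack.pop()
        items.append((d, tree.labels[v]))
        for c in reversed(tree.children[v]):
            stack.append((c, d + 1))
    return DepthLabelSequence(tuple(items))


def compare_sequences(
    a: DepthLabelSequence, b: DepthLabelSequence, alphabet: Alphabet
) -> int:
    """Lexicographic comparison; returns -1, 0 or +1."""
    ka = tuple(_pair_key(d, l, alphabet) for d, l in a.items)
    kb = tuple(_pair_key(d, l, alphabet) for d, l in b.items)
    return (ka > kb) - (ka < kb)


def _subtree_keys(tree: RootedTree, v: int, alphabet: Alphabet):
    """Yield pair keys of the subtree at ``v`` with depths relative to ``v``."""
    stack = [(v, 0)]
    while stack:
        u, d = stack.pop()
        yield _pair_key(d, tree.labels[u], alphabet)
        for c in reversed(tree.children[u]):
            stack.append((c, d + 1))


def _seq_geq(tree: RootedTree, a: int, b: int, alphabet: Alphabet) -> bool:
    """True iff subtree sequence at ``a`` >= subtree sequence at ``b``."""
    ita, itb = _subtree_keys(tree, a, alphabet), _subtree_keys(tree, b, alphabet)
    for ka, kb in zip(ita, itb):
        if ka != kb:
            return ka > kb
    # common part equal: the longer sequence is larger (prefix rule)
    return next(itb, None) is None


def is_left_heavy(tree: RootedTree, alphabet: Alphabet) -> bool:
    """True iff every vertex's child subtrees are in non-increasing order."""
    for v in range(len(tree.labels)):
        ch = tree.children[v]
        for a, b in zip(ch, ch[1:]):
            if not _seq_geq(tree, a, b, alphabet):
                return False
    return True


def find_centroid(tree: MultiTreeSolution) -> Centroid:
    n = tree.n
    adj = tree.adjacency()
    if n == 1:
        return Centroid("unicentroid", (0,))
    # subtree sizes from an arbitrary root (vertex 0), iterative post-order
    parent = [-1] * n
    order: list[int] = []
    stack = [0]
    seen = [False] * n
    seen[0] = True
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adj[v]:
            if not seen[w]:
                seen[w] = True
                parent[w] = v
                stack.append(w)
    size = [1] * n
    for v in reversed(order):
        if parent[v] >= 0:
            size[parent[v]] += size[v]
    half = (n - 1) // 2
    for v in range(n):
        comps = [size[w] for w in adj[v] if parent[w] == v]
        if parent[v] >= 0:
            comps.append(n - size[v])
        if max(comps) <= half:
            return Centroid("unicentroid", (v,))
    for v in range(n):
        p = parent[v]
        if p >= 0 and 2 * size[v] == n:
            return Centroid("bicentroid", (min(p, v), max(p, v)))
    raise AssertionError("Jordan's theorem guarantees a centroid")  # pragma: no cover


def _rooted_form(
    tree: MultiTreeSolution,
    alphabet: Alphabet,
    v: int,
    banned: int,
    mults: dict[tuple[int, int], int],
    mult_up: int,
):
    """Canonical nested-tuple form of the sub-multitree at ``v`` away from ``banned``."""
    adj = tree.adjacency()

    def form(u: int, prev: int, m_up: int):
        kids = sorted(
            (
                form(w, u, mults[(min(u, w), max(u, w))])
                for w in adj[u]
                if w != prev
            ),
            reverse=True,
        )
        return (alphabet.size - alphabet.index(tree.vertices[u]), m_up, tuple(kids))

    return form(v, banned, mult_up)


def canonical_key(tree: MultiTreeSolution, alphabet: Alphabet):
    """Isomorphism-invariant total key of a labeled multitree.

    Rooted at the centroid; multiplicities are part of the key, so two
    multitrees compare equal exactly when a label- and multiplicity-
    preserving isomorphism exists between them.
    """
    mults = {(min(a, b), max(a, b)): m for a, b, m in tree.edges}
    c = find_centroid(tree)
    if c.kind == "unicentroid":
        return ("u", _rooted_form(tree, alphabet, c.vertices[0], -1, mults, 0))
    u, v = c.vertices
    bridge = mults[(u, v)]
    fu = _rooted_form(tree, alphabet, u, v, mults, 0)
    fv = _rooted_form(tree, alphabet, v, u, mults, 0)
    hi, lo = (fu, fv) if fu >= fv else (fv, fu)
    return ("b", bridge, hi, lo)


def key_string(key) -> str:
    """Stable printable identifier for a canonical key."""
    return repr(key)
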
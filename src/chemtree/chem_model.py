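"""Core domain types: label alphabets, chemical multitrees, enumeration instances.

A chemical compound is modelled as a connected multigraph that is acyclic once
parallel edges are collapsed ("multitree"), whose vertices carry element labels
and whose degree -- counting bond multiplicity -- equals the valence of the
label at every vertex.  An enumeration instance asks for every such multitree
(up to isomorphism) whose path-frequency feature vector of level ``K`` lies
between two bound vectors ``g_L <= f_K(T) <= g_U``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Alphabet",
    "MultiTreeSolution",
    "Instance",
    "InstanceError",
    "validate_instance",
    "parse_sequence_key",
    "format_sequence_key",
]

#: delimiter between labels in textual label-sequence keys ("C-C-O")
KEY_DELIMITER = "-"


class InstanceError(ValueError):
    """Raised when an instance description violates a precondition."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered label set with a valence for every label.

    The declared order of ``labels`` is the total order that drives every
    lexicographic comparison in the canonical-form machinery; permuting it
    changes traversal order but never the enumerated solution set.
    """

    labels: tuple[str, ...]
    valence: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise InstanceError("alphabet labels must be unique")
        for lab in self.labels:
            v = self.valence.get(lab)
            if v is None:
                raise InstanceError(f"label {lab!r} has no valence")
            if not isinstance(v, int) or v < 1:
                raise InstanceError(f"valence of {lab!r} must be a positive integer")
        extra = set(self.valence) - set(self.labels)
        if extra:
            raise InstanceError(f"valence given for unknown labels {sorted(extra)}")
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]  # type: ignore[attr-defined]
        except KeyError:
            raise InstanceError(f"unknown label {label!r}") from None

    def val(self, label: str) -> int:
        self.index(label)  # raises for unknown labels
        return self.valence[label]

    def val_by_index(self, i: int) -> int:
        return self.valence[self.labels[i]]


@dataclass(frozen=True)
class MultiTreeSolution:
    """A finished chemical multitree.

    ``vertices`` maps DFS-independent indices ``0..n-1`` to labels; ``edges``
    is a list of ``(u, v, multiplicity)`` with ``u < v``.  The simple graph on
    the ``(u, v)`` pairs must be a tree and every vertex's multiplicity-counted
    degree must equal the valence of its label.
    """

    vertices: tuple[str, ...]
    edges: tuple[tuple[int, int, int], ...]

    @property
    def n(self) -> int:
        return len(self.vertices)

    def degree(self, v: int) -> int:
        return sum(m for a, b, m in self.edges if v in (a, b))

    def adjacency(self) -> list[list[int]]:
        """Neighbour lists of the multiplicity-collapsed simple tree."""
        adj: list[list[int]] = [[] for _ in self.vertices]
        for a, b, _ in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def validate(self, alphabet: Alphabet) -> None:
        n = self.n
        if n == 0:
            raise InstanceError("empty solution")
        if len(self.edges) != n - 1:
            raise InstanceError("edge count must be n - 1 (simple-tree condition)")
        seen = set()
        for a, b, m in self.edges:
            if a == b:
                raise InstanceError("self-loop in solution")
            if not (0 <= a < n and 0 <= b < n):
                raise InstanceError("edge endpoint out of range")
            if m < 1:
                raise InstanceError("edge multiplicity must be >= 1")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise InstanceError("parallel edge listed twice")
            seen.add(key)
        # connectivity (n-1 distinct simple edges + connected => tree)
        adj = self.adjacency()
        stack, reached = [0], {0}
        while stack:
            for w in adj[stack.pop()]:
                if w not in reached:
                    reached.add(w)
                    stack.append(w)
        if len(reached) != n:
            raise InstanceError("solution not connected")
        for v, lab in enumerate(self.vertices):
            if self.degree(v) != alphabet.valence[lab]:
                raise InstanceError(
                    f"vertex {v} ({lab}) has degree {self.degree(v)} != valence"
                )


def parse_sequence_key(key: str) -> tuple[str, ...]:
    """Split a textual label-sequence key like ``"C-C-O"``."""
    parts = tuple(p for p in key.split(KEY_DELIMITER) if p)
    if not parts:
        raise InstanceError(f"empty label-sequence key {key!r}")
    return parts


def format_sequence_key(seq: Sequence[str]) -> str:
    return KEY_DELIMITER.join(seq)


@dataclass
class Instance:
    """A validated enumeration instance.

    ``g_l`` / ``g_u`` map label sequences (tuples of labels, length 1..K+1) to
    integer bounds.  Sequences absent from ``g_l`` are unconstrained below
    (bound 0).  Sequences absent from ``g_u`` default to ``upper_default``:
    ``math.inf`` for hand-written bound files, ``0`` for instances built by
    widening a realized feature vector, where unseen sequences are genuinely
    forbidden.
    """

    alphabet: Alphabet
    K: int
    g_l: dict[tuple[str, ...], int]
    g_u: dict[tuple[str, ...], int]
    upper_default: float = math.inf  # 0 or inf
    n: int = field(init=False)
    M: int = field(init=False)

    def __post_init__(self) -> None:
        self.n = sum(self.g_u.get((lab,), 0) for lab in self.alphabet.labels)
        deg_sum = sum(
            self.alphabet.valence[lab] * self.g_u.get((lab,), 0)
            for lab in self.alphabet.labels
        )
        self.M = deg_sum // 2 - (self.n - 1)

    def count(self, label: str) -> int:
        """Number of vertices of ``label`` in every solution (atom counts fixed)."""
        return self.g_u.get((label,), 0)

    def upper(self, seq: tuple[str, ...]) -> float:
        u = self.g_u.get(seq)
        if u is not None:
            return u
        if len(seq) == 1:
            return 0
        if len(seq) > self.K + 1:  # beyond the instance's level: unconstrained
            return math.inf
        return self.upper_default

    def lower(self, seq: tuple[str, ...]) -> int:
        return self.g_l.get(seq, 0)


def _symmetrize(
    g_l: dict[tuple[str, ...], int],
    g_u: dict[tuple[str, ...], int],
    upper_default: float,
) -> None:
    """Tighten bounds using #t = #reverse(t), which holds for every realized vector.

    For the upper vector the effective bound of an orientation pair is the min
    of the two (a missing entry means ``upper_default``); for the lower vector
    the max.  Mutates the dicts in place.
    """
    for g, pick, dflt in ((g_u, min, upper_default), (g_l, max, 0)):
        for seq in list(g):
            rev = seq[::-1]
            if rev == seq:
                continue
            other = g.get(rev, dflt)
            best = pick(g[seq], other)
            if best is not math.inf:
                g[seq] = int(best)
                g[rev] = int(best)
            else:
                g.pop(seq, None)
                g.pop(rev, None)


def validate_instance(raw: Mapping) -> Instance:
    """Build a validated :class:`Instance` from a raw description.

    ``raw`` must supply ``alphabet`` (label -> valence), ``K`` and the bound
    maps ``g_L``/``g_U`` whose keys are either label tuples or delimited
    strings.  Optional keys: ``order`` (explicit label order, default sorted
    insertion order of ``alphabet``) and ``g_U_default`` (``"inf"`` or ``0``).
    Passing an :class:`Instance` returns it unchanged (idempotence).
    """
    if isinstance(raw, Instance):
        return raw
    try:
        alpha_map = dict(raw["alphabet"])
        K = int(raw["K"])
        raw_l = dict(raw["g_L"])
        raw_u = dict(raw["g_U"])
    except KeyError as exc:
        raise InstanceError(f"instance description missing key {exc}") from None
    order = tuple(raw.get("order", list(alpha_map)))
    alphabet = Alphabet(order, alpha_map)
    if K < 0:
        raise InstanceError("level K must be non-negative")
    dflt = raw.get("g_U_default", "inf")
    upper_default: float = math.inf if str(dflt) in ("inf", "Infinity") else 0

    def norm(bounds: Mapping) -> dict[tuple[str, ...], int]:
        out: dict[tuple[str, ...], int] = {}
        for key, value in bounds.items():
            seq = parse_sequence_key(key) if isinstance(key, str) else tuple(key)
            for lab in seq:
                alphabet.index(lab)  # raises for unknown labels
            if len(seq) > K + 1:
                raise InstanceError(
                    f"sequence {format_sequence_key(seq)!r} longer than level K + 1"
                )
            if int(value) < 0:
                raise InstanceError("negative bound entry")
            out[seq] = int(value)
        return out

    g_l, g_u = norm(raw_l), norm(raw_u)

    for lab in alphabet.labels:
        lo, up = g_l.get((lab,)), g_u.get((lab,))
        if lo is None or up is None:
            raise InstanceError(f"atom count for {lab!r} must appear in both bounds")
        if lo != up:
            raise InstanceError(
                f"atom-count bounds differ for {lab!r} (counts are fixed)"
            )

    # drop entries that mention exhausted labels: they can only be zero
    zero_labels = {lab for lab in alphabet.labels if g_u[(lab,)] == 0}
    for g in (g_l, g_u):
        for seq in list(g):
            if len(seq) > 1 and zero_labels.intersection(seq):
                if g is g_l and g[seq] > 0:
                    raise InstanceError(
                        f"lower bound on {format_sequence_key(seq)!r} uses a label "
                        "with atom count 0"
                    )
                del g[seq]

    _symmetrize(g_l, g_u, upper_default)

    for seq, lo in g_l.items():
        if lo > (g_u.get(seq, upper_default if len(seq) > 1 else 0)):
            raise InstanceError(
                f"bounds inverted for {format_sequence_key(seq)!r}: g_L > g_U"
            )

    inst = Instance(alphabet, K, g_l, g_u, upper_default)
    if inst.n < 1:
        raise InstanceError("instance has no vertices")
    deg_sum = sum(alphabet.valence[l] * inst.count(l) for l in alphabet.labels)
    if deg_sum % 2:
        raise InstanceError("odd total valence sum: no multigraph realizes it")
    if inst.M < 0:
        raise InstanceError(
            "negative multiplicity budget: fewer bond units than tree edges"
        )
    return inst
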
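"""Brute-force reference enumeration for small instances.

Every labeled tree shape on a fixed vertex multiset is generated through
Prüfer sequences; the valence constraint forces all edge multiplicities
bottom-up, infeasible shapes are dropped, and duplicates are removed by the
canonical key.  Deliberately simple and independent of the branch-and-bound
path: exhaustiveness of the Prüfer encoding is a textbook fact, so the result
is the complete isomorph-free solution set and the main enumerator can be
checked against it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from . import canonical
from .chem_model import Alphabet, Instance, InstanceError, MultiTreeSolution
from .feature_vector import count_paths

__all__ = ["OracleResult", "all_multitrees", "oracle_count", "oracle_result"]

_HARD_CAP = 9


@dataclass
class OracleResult:
    all_keys: set
    filtered_keys: set
    solutions: list[MultiTreeSolution]

    @property
    def count(self) -> int:
        return len(self.filtered_keys)


def _forced_multiplicities(
    n: int, labels: list[str], adj: list[list[int]], alphabet: Alphabet
) -> list[tuple[int, int, int]] | None:
    """Unique edge multiplicities giving degree = valence, or None.

    Rooted at 0; each vertex's edge toward the root must absorb exactly the
    valence its closed subtree edges leave over, so the assignment is forced
    leaf-to-root and either works everywhere or nowhere.
    """
    parent = [-1] * n
    order = [0]
    seen = [False] * n
    seen[0] = True
    for v in order:
        for w in adj[v]:
            if not seen[w]:
                seen[w] = True
                parent[w] = v
                order.append(w)
    used = [0] * n
    edges: list[tuple[int, int, int]] = []
    for v in reversed(order):
        p = parent[v]
        if p < 0:
            if used[v] != alphabet.valence[labels[v]]:
                return None
            continue
        m = alphabet.valence[labels[v]] - used[v]
        if m < 1:
            return None
        used[v] += m
        used[p] += m
        edges.append((min(v, p), max(v, p), m))
    return sorted(edges)


def all_multitrees(
    formula: Mapping[str, int], alphabet: Alphabet
) -> list[MultiTreeSolution]:
    """Every valence-valid multitree on the given atom counts, up to isomorphism.

    Iterates over all Prüfer sequences compatible with the valences (a vertex
    of valence ``val`` appears at most ``val - 1`` times, so valence-1 atoms
    never appear), forces multiplicities, and deduplicates canonically.
    """
    labels: list[str] = []
    for lab in alphabet.labels:
        labels.extend([lab] * formula.get(lab, 0))
    n = len(labels)
    if n > _HARD_CAP:
        raise InstanceError(f"oracle capped at {_HARD_CAP} vertices")
    if n == 0:
        return []
    deg_sum = sum(alphabet.valence[l] for l in labels)
    if deg_sum % 2:
        raise InstanceError("odd valence sum")
    out: dict = {}
    if n == 1:
        if alphabet.valence[labels[0]] == 0:  # pragma: no cover - valences >= 1
            out["single"] = MultiTreeSolution((labels[0],), ())
        return list(out.values())

    caps = [alphabet.valence[l] - 1 for l in labels]

    def seqs(pos: int, prefix: list[int], left: list[int]):
        if pos == n - 2:
            yield tuple(prefix)
            return
        for v in range(n):
            if left[v] > 0:
                left[v] -= 1
                prefix.append(v)
                yield from seqs(pos + 1, prefix, left)
                prefix.pop()
                left[v] += 1

    for seq in seqs(0, [], caps):
        if n == 2:
            tree = nx.Graph([(0, 1)])
        else:
            tree = nx.from_prufer_sequence(list(seq))
        adj = [list(tree.neighbors(v)) for v in range(n)]
        edges = _forced_multiplicities(n, labels, adj, alphabet)
        if edges is None:
            continue
        sol = MultiTreeSolution(tuple(labels), tuple(edges))
        key = canonical.canonical_key(sol, alphabet)
        out.setdefault(key, sol)
    return list(out.values())


def oracle_result(inst: Instance) -> OracleResult:
    """All valence-valid multitrees of the instance's formula, plus the subset
    inside the feature-vector box."""
    formula = {lab: inst.count(lab) for lab in inst.alphabet.labels}
    candidates = all_multitrees(formula, inst.alphabet)
    all_keys, filtered_keys, solutions = set(), set(), []
    for sol in candidates:
        key = canonical.canonical_key(sol, inst.alphabet)
        all_keys.add(key)
        fv = count_paths(sol, inst.K)
        ok = all(c <= inst.upper(t) for t, c in fv.items()) and all(
            fv[t] >= lo for t, lo in inst.g_l.items()
        )
        if ok:
            filtered_keys.add(key)
            solutions.append(sol)
    return OracleResult(all_keys, filtered_keys, solutions)


def oracle_count(inst: Instance) -> int:
    return oracle_result(inst).count
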
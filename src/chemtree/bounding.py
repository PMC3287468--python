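"""Pruning operations on search states.

A state is discarded as soon as it can be shown that no descendant is a valid
output: the root would stop being the centroid (centroid-cut), some vertex
already exceeds its valence or a forced closing multiplicity drops below one
(valence-cut), some feature-vector entry exceeds its upper bound -- and, at
full size, some entry misses its lower bound (feature-vector-cut), the closed
multiple-bond units exceed the instance budget M (multiplicity-cut), or the
remaining vertices cannot be attached consistently with the pair bounds
(detachment-cut, in :mod:`chemtree.detachment`).  Every cut only removes dead
branches: disabling any subset changes visited-node counts, never the emitted
solution set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .branching import SearchTree
from .chem_model import Instance

__all__ = [
    "CutConfig",
    "centroid_cut",
    "valence_cut",
    "feature_vector_cut",
    "multiplicity_cut",
]


@dataclass
class CutConfig:
    """Which cuts run; all on by default.  ``detachment_stride`` applies the
    (comparatively expensive) detachment-cut only at every k-th tree size."""

    centroid: bool = True
    valence: bool = True
    feature: bool = True
    detachment: bool = True
    multiplicity: bool = True
    detachment_stride: int = 1

    def disable(self, name: str) -> "CutConfig":
        if not hasattr(self, name):
            raise ValueError(f"unknown cut {name!r}")
        setattr(self, name, False)
        return self


def centroid_cut(T: SearchTree, n: int) -> bool:
    """Keep (True) unless the root has already lost the centroid property.

    Jordan's bound: every subtree hanging off the centroid of an ``n``-vertex
    tree has at most ``floor((n-1)/2)`` vertices.  Subtree sizes only grow, so
    a root child subtree past the bound can never recover.  The check is
    conservative; an exact centroid test runs on every completed tree.
    """
    half = (n - 1) // 2
    root = T.sub_root
    return all(T.size[c] <= half for c in T.children[root])


def valence_cut(T: SearchTree) -> bool:
    """Keep iff no vertex uses more bond capacity than its valence allows.

    Maintained incrementally by :meth:`SearchTree.extend`; this standalone
    form re-derives the verdict for a whole state (used in tests and by the
    spec-level ``children`` surface).
    """
    for v in range(len(T)):
        opens = sum(1 for c in T.children[v] if T.mult[c] is None)
        if T.parent[v] >= 0 and T.mult[v] is None:
            opens += 1
        if T.used[v] + opens > T.vals[T.label[v]]:
            return False
    return True


def feature_vector_cut(T: SearchTree, inst: Instance) -> bool:
    """Keep iff ``f_K(T) <= g_U`` and, at full size, ``g_L <= f_K(T)``."""
    for t, c in T.f.items():
        if c > T.upper(t):
            return False
    if len(T) == inst.n and not T.lower_ok():
        return False
    return True


def multiplicity_cut(T: SearchTree, M: int) -> bool:
    """Keep iff the multiple-bond units already fixed stay within budget M."""
    return T.m_running <= M
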
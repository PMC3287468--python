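"""The enumeration driver: exact, isomorph-free, branch-and-bound.

Every free tree has a unique centroid (Jordan): a vertex, or -- only for an
even vertex count -- an edge.  Solutions are therefore produced in two
disjoint passes.  The unicentroid pass grows left-heavy trees rooted at the
future centroid by appending leaves along the rightmost path, pruning with
the bounding operations, and keeps a completed tree only if its root really
is the centroid.  The bicentroid pass builds an ordered pair of left-heavy
halves of ``n/2`` vertices joined by a bridge edge whose multiplicity is
forced by both roots' residual valences; the pair is kept once, with the
first half's depth-label sequence >= the second's.  Together the passes emit
every solution of the instance exactly once up to isomorphism, in a
deterministic order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterator, Optional

from . import branching, canonical
from .bounding import CutConfig, centroid_cut, multiplicity_cut
from .branching import SearchTree
from .chem_model import Instance, MultiTreeSolution
from .detachment import detachment_cut

__all__ = [
    "RunReport",
    "enumerate_solutions",
    "enumerate_bicentroid",
    "run",
    "count_solutions",
]


@dataclass
class RunReport:
    """Counters of one enumeration run (mirrors the usual nodes/solutions
    accounting of branch-and-bound structure generators)."""

    nodes: int = 0
    solutions: int = 0
    prunes: dict = field(default_factory=dict)
    elapsed: float = 0.0
    config: Optional[CutConfig] = None

    def prune(self, reason: str) -> None:
        self.prunes[reason] = self.prunes.get(reason, 0) + 1


class _Driver:
    def __init__(self, inst: Instance, cfg: Optional[CutConfig]):
        self.inst = inst
        self.cfg = cfg or CutConfig()
        self.report = RunReport(config=self.cfg)
        self.s = inst.alphabet.size

    # ------------------------------------------------------------ unicentroid
    def _solutions_uni(self) -> Iterator[MultiTreeSolution]:
        T = SearchTree(self.inst)
        for lab in range(self.s):
            rec = T.extend_root(lab, check_upper=self.cfg.feature)
            if rec is None:
                continue
            if rec.fail:
                self.report.prune(rec.fail)
                continue
            self.report.nodes += 1
            yield from self._dfs_uni(T)
            T.undo(rec)

    def _dfs_uni(self, T: SearchTree) -> Iterator[MultiTreeSolution]:
        inst, cfg = self.inst, self.cfg
        if len(T) == inst.n:
            sol = branching.finalize(T, inst)
            if sol is None:
                self.report.prune("final")
                return
            c = canonical.find_centroid(sol)
            if c.kind != "unicentroid" or c.vertices != (0,):
                self.report.prune("centroid-final")
                return
            self.report.solutions += 1
            yield sol
            return
        for i in range(len(T.rp)):
            for lab in range(self.s):
                rec = T.extend(i, lab, check_upper=cfg.feature)
                if rec is None:
                    continue
                if rec.fail:
                    self.report.prune(rec.fail)
                    continue
                self.report.nodes += 1
                if cfg.multiplicity and not multiplicity_cut(T, inst.M):
                    self.report.prune("multiplicity")
                elif cfg.centroid and not centroid_cut(T, inst.n):
                    self.report.prune("centroid")
                elif (
                    cfg.detachment
                    and len(T) % max(1, cfg.detachment_stride) == 0
                    and not detachment_cut(T, inst)
                ):
                    self.report.prune("detachment")
                else:
                    yield from self._dfs_uni(T)
                T.undo(rec)

    # ------------------------------------------------------------- bicentroid
    def _solutions_bi(self) -> Iterator[MultiTreeSolution]:
        if self.inst.n % 2 or self.inst.n < 2:
            return
        T = SearchTree(self.inst)
        for lab in range(self.s):
            rec = T.extend_root(lab, check_upper=self.cfg.feature)
            if rec is None:
                continue
            if rec.fail:
                self.report.prune(rec.fail)
                continue
            self.report.nodes += 1
            yield from self._dfs_half1(T)
            T.undo(rec)

    def _dfs_half1(self, T: SearchTree) -> Iterator[MultiTreeSolution]:
        inst, cfg = self.inst, self.cfg
        n2 = inst.n // 2
        if len(T) == n2:
            yield from self._half1_complete(T)
            return
        for i in range(len(T.rp)):
            for lab in range(self.s):
                rec = T.extend(i, lab, check_upper=cfg.feature)
                if rec is None:
                    continue
                if rec.fail:
                    self.report.prune(rec.fail)
                    continue
                self.report.nodes += 1
                if cfg.multiplicity and not multiplicity_cut(T, inst.M):
                    self.report.prune("multiplicity")
                else:
                    yield from self._dfs_half1(T)
                T.undo(rec)

    def _half1_complete(self, T: SearchTree) -> Iterator[MultiTreeSolution]:
        """Close the first half, then grow the second across the bridge."""
        inst, cfg = self.inst, self.cfg
        res = T.closing_plan()
        if res is None:
            self.report.prune("final")
            return
        plan, b1 = res
        if b1 < 1:
            self.report.prune("final")
            return
        if cfg.multiplicity and T.m_running + sum(m - 1 for _, m in plan) + (
            b1 - 1
        ) > inst.M:
            self.report.prune("multiplicity")
            return
        T.apply_closing(plan)
        old_rp = T.rp
        T.rp = []  # the bridge root starts a fresh rightmost path
        h1_keys = T.dls_keys(0)
        for lab in range(self.s):
            if inst.alphabet.valence[inst.alphabet.labels[lab]] < b1:
                continue  # the bridge alone would exceed this root's valence
            key0 = (0, self.s - lab)
            if key0 > h1_keys[0]:
                continue  # second half would outrank the first: mirror pair
            rec = T.extend_bridge_root(lab, check_upper=cfg.feature)
            if rec is None:
                continue
            if rec.fail:
                self.report.prune(rec.fail)
                continue
            self.report.nodes += 1
            yield from self._dfs_half2(T, b1, h1_keys, key0 == h1_keys[0])
            T.undo(rec)
        T.rp = old_rp
        T.revert_closing(plan)

    def _dfs_half2(
        self,
        T: SearchTree,
        b1: int,
        h1_keys: tuple,
        tight: bool,
    ) -> Iterator[MultiTreeSolution]:
        inst, cfg = self.inst, self.cfg
        n2 = inst.n // 2
        if len(T) == inst.n:
            yield from self._half2_complete(T, b1)
            return
        for i in range(len(T.rp)):
            for lab in range(self.s):
                rec = T.extend(i, lab, check_upper=cfg.feature)
                if rec is None:
                    continue
                if rec.fail:
                    self.report.prune(rec.fail)
                    continue
                u = len(T) - 1
                pos = len(T) - n2 - 1  # index of the new depth-label pair
                key = (T.depth[u], self.s - lab)
                if tight and key > h1_keys[pos]:
                    self.report.prune("mirror")
                    T.undo(rec)
                    continue
                self.report.nodes += 1
                if cfg.multiplicity and not multiplicity_cut(T, inst.M):
                    self.report.prune("multiplicity")
                else:
                    yield from self._dfs_half2(
                        T, b1, h1_keys, tight and key == h1_keys[pos]
                    )
                T.undo(rec)

    def _half2_complete(self, T: SearchTree, b1: int) -> Iterator[MultiTreeSolution]:
        inst = self.inst
        res = T.closing_plan()
        if res is None:
            self.report.prune("final")
            return
        plan, b2 = res
        if b2 != b1:
            self.report.prune("final")
            return
        if not (T.lower_ok() and T.upper_ok()):
            self.report.prune("final")
            return
        root2 = T.sub_root
        T.apply_closing(plan)
        try:
            sol = T.to_solution(extra_edges=[(0, root2, b1)])
        finally:
            T.revert_closing(plan)
        self.report.solutions += 1
        yield sol


def enumerate_solutions(
    inst: Instance,
    cfg: Optional[CutConfig] = None,
    report: Optional[RunReport] = None,
    max_solutions: Optional[int] = None,
) -> Iterator[MultiTreeSolution]:
    """Stream every solution of ``inst`` exactly once up to isomorphism.

    The unicentroid pass runs for every ``n``; the bicentroid pass only for
    even ``n``.  ``report``, if given, is filled with counters in place.
    """
    drv = _Driver(inst, cfg)
    if report is not None:
        drv.report = report
        report.config = drv.cfg
    t0 = time.perf_counter()
    emitted = 0
    for sol in drv._solutions_uni():
        yield sol
        emitted += 1
        if max_solutions is not None and emitted >= max_solutions:
            drv.report.elapsed = time.perf_counter() - t0
            return
    for sol in drv._solutions_bi():
        yield sol
        emitted += 1
        if max_solutions is not None and emitted >= max_solutions:
            break
    drv.report.elapsed = time.perf_counter() - t0


def enumerate_bicentroid(
    inst: Instance, cfg: Optional[CutConfig] = None
) -> Iterator[MultiTreeSolution]:
    """Only the solutions whose centroid is an edge (empty for odd ``n``)."""
    drv = _Driver(inst, cfg)
    yield from drv._solutions_bi()


def run(
    inst: Instance,
    cfg: Optional[CutConfig] = None,
    max_solutions: Optional[int] = None,
) -> tuple[list[MultiTreeSolution], RunReport]:
    report = RunReport()
    sols = list(
        enumerate_solutions(inst, cfg, report=report, max_solutions=max_solutions)
    )
    return sols, report


def count_solutions(inst: Instance, cfg: Optional[CutConfig] = None) -> int:
    n = 0
    for _ in enumerate_solutions(inst, cfg):
        n += 1
    return n
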
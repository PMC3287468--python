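"""Molecule files, instance files, solution output, synthetic fixtures.

Molecules come in as MDL MOL/SDF (first record) through RDKit.  Preprocessing
follows the hydrogen-explicit convention -- implicit hydrogen counts are
expanded into real vertices -- and optionally contracts each isolated plain
benzene ring into one virtual atom of valence six that inherits the ring's
external bonds and ring hydrogens, which is what makes monocyclic aromatics
tree-like.  Anything else cyclic (fused rings, heteroaromatics, aliphatic
rings) is a hard error, never a silent guess.

Instance files are YAML/JSON maps (``alphabet``, ``order``, ``K``, ``g_L``,
``g_U``) with label sequences spelled ``"C-C-O"``.  Solutions go out as SDF
(bond orders = multiplicities) or as one canonical key per line.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import yaml
from rdkit import Chem
from rdkit import RDLogger

from . import canonical
from .chem_model import (
    Alphabet,
    Instance,
    InstanceError,
    MultiTreeSolution,
    format_sequence_key,
    validate_instance,
)
from .feature_vector import count_paths, widen

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "PreprocessConfig",
    "LoadedMolecule",
    "read_molecule",
    "make_instance",
    "write_solutions",
    "solution_to_molblock",
    "synth_tree",
    "synth_instance",
    "load_instance",
    "save_instance",
    "instance_to_dict",
]


@dataclass(frozen=True)
class PreprocessConfig:
    contract_benzene: bool = True
    virtual_label: str = "bz"
    virtual_valence: int = 6

    def __post_init__(self) -> None:
        if self.contract_benzene and self.virtual_valence != 6:
            raise InstanceError("the benzene virtual atom has valence six")


@dataclass(frozen=True)
class LoadedMolecule:
    tree: MultiTreeSolution
    alphabet: Alphabet


class MoleculeError(ValueError):
    """Raised when a structure cannot be brought into multitree form."""


def _first_molblock(text: str) -> str:
    return text.split("$$$$")[0]


def _parse_rdkit(text: str):
    mol = Chem.MolFromMolBlock(text, removeHs=False)
    if mol is not None:
        return Chem.AddHs(mol)
    mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        raise MoleculeError("RDKit could not parse the MOL block")
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def _benzene_rings(mol) -> list[tuple[int, ...]]:
    """Atom index tuples of plain, isolated benzene rings."""
    info = mol.GetRingInfo()
    rings = [tuple(r) for r in info.AtomRings()]
    benz: list[tuple[int, ...]] = []
    for ring in rings:
        if len(ring) != 6:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if any(a.GetSymbol() != "C" for a in atoms):
            continue
        bonds = []
        rs = set(ring)
        for b in mol.GetBonds():
            if b.GetBeginAtomIdx() in rs and b.GetEndAtomIdx() in rs:
                bonds.append(b)
        if len(bonds) != 6:
            continue  # extra chords: not a plain ring
        orders = sorted(b.GetBondTypeAsDouble() for b in bonds)
        if all(o == 1.5 for o in orders) or orders == [1, 1, 1, 2, 2, 2]:
            benz.append(ring)
    counts: dict[int, int] = {}
    for ring in benz:
        for i in ring:
            counts[i] = counts.get(i, 0) + 1
    for ring in benz:
        if any(counts[i] > 1 for i in ring):
            raise MoleculeError("fused aromatic rings are not contractible")
    return benz


def read_molecule(
    source: str | Path, cfg: Optional[PreprocessConfig] = None
) -> LoadedMolecule:
    """Read a MOL/SDF structure into a valence-exact multitree.

    Implicit hydrogens are expanded; benzene rings are contracted to virtual
    atoms (when enabled); the result must be acyclic with every same-label
    vertex showing the same multiplicity-counted degree, which becomes the
    label's valence.
    """
    cfg = cfg or PreprocessConfig()
    text = Path(source).read_text() if not str(source).count("\n") else str(source)
    mol = _parse_rdkit(_first_molblock(text))

    labels: dict[int, str] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        labels[atom.GetIdx()] = cfg.virtual_label if sym == "*" else sym
    edges: dict[tuple[int, int], int] = {}
    nonint: set[tuple[int, int]] = set()
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        key = (min(u, v), max(u, v))
        o = b.GetBondTypeAsDouble()
        if o != int(o):
            nonint.add(key)
            o = 0
        edges[key] = int(o)

    ring_of: dict[int, int] = {}
    rings = _benzene_rings(mol) if cfg.contract_benzene else []
    for ri, ring in enumerate(rings):
        for i in ring:
            ring_of[i] = ri

    for (u, v), o in edges.items():
        inside = ring_of.get(u) is not None and ring_of.get(u) == ring_of.get(v)
        if (u, v) in nonint and not inside:
            raise MoleculeError("aromatic bond outside a contractible benzene ring")
        if o < 1 and not inside:
            raise MoleculeError("unsupported bond order")

    # vertex set after contraction
    new_id: dict[int | str, int] = {}
    out_labels: list[str] = []
    for i in sorted(labels):
        if i in ring_of:
            continue
        new_id[i] = len(out_labels)
        out_labels.append(labels[i])
    for ri in range(len(rings)):
        new_id[f"ring{ri}"] = len(out_labels)
        out_labels.append(cfg.virtual_label)

    def target(i: int):
        return new_id[f"ring{ring_of[i]}"] if i in ring_of else new_id[i]

    out_edges: dict[tuple[int, int], int] = {}
    for (u, v), o in edges.items():
        tu, tv = target(u), target(v)
        if tu == tv:
            continue  # ring-internal bond vanishes into the virtual atom
        key = (min(tu, tv), max(tu, tv))
        if key in out_edges:
            raise MoleculeError("residual cycle after benzene contraction")
        out_edges[key] = o

    if len(out_edges) != len(out_labels) - 1:
        raise MoleculeError("residual cycle after benzene contraction")
    tree = MultiTreeSolution(
        tuple(out_labels), tuple((u, v, m) for (u, v), m in sorted(out_edges.items()))
    )
    # derive valences from observed degrees and check consistency
    valences: dict[str, int] = {}
    for v, lab in enumerate(out_labels):
        d = tree.degree(v)
        if valences.setdefault(lab, d) != d:
            raise MoleculeError(
                f"label {lab!r} appears with inconsistent degrees; "
                "the valence model does not apply"
            )
    if cfg.contract_benzene and cfg.virtual_label in valences:
        if valences[cfg.virtual_label] != cfg.virtual_valence:
            raise MoleculeError("contracted ring degree is not six")
    order = tuple(sorted(valences))
    alphabet = Alphabet(order, valences)
    try:
        tree.validate(alphabet)
    except InstanceError as exc:
        raise MoleculeError(str(exc)) from exc
    return LoadedMolecule(tree, alphabet)


def make_instance(mol: LoadedMolecule, K: int, w: int) -> Instance:
    """Widen the molecule's level-K feature vector into an instance of width w."""
    fv = count_paths(mol.tree, K)
    g_l, g_u = widen(fv, w)
    for lab in mol.alphabet.labels:  # unused labels have a fixed count of 0
        g_l.setdefault((lab,), 0)
        g_u.setdefault((lab,), 0)
    raw = {
        "alphabet": dict(mol.alphabet.valence),
        "order": list(mol.alphabet.labels),
        "K": K,
        "g_L": dict(g_l),
        "g_U": dict(g_u),
        "g_U_default": 0,
    }
    return validate_instance(raw)


_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def solution_to_molblock(sol: MultiTreeSolution, alphabet: Alphabet) -> str:
    """One MOL V2000 block; non-element labels become dummy atoms ``*``.

    Bond multiplicities above 3 have no MDL bond-order encoding and are
    rejected.
    """
    pt = Chem.GetPeriodicTable()
    rw = Chem.RWMol()
    for lab in sol.vertices:
        try:
            num = pt.GetAtomicNumber(lab)
        except Exception:
            num = 0
        atom = Chem.Atom(num)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for u, v, m in sol.edges:
        if m not in _BOND_TYPES:
            raise InstanceError(f"multiplicity {m} not representable in MOL format")
        rw.AddBond(u, v, _BOND_TYPES[m])
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    return Chem.MolToMolBlock(mol, kekulize=False)


def write_solutions(
    solutions: Iterable[MultiTreeSolution],
    path: str | Path,
    fmt: str = "sdf",
    alphabet: Optional[Alphabet] = None,
) -> int:
    """Write a solution stream to ``path``; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for sol in solutions:
            if alphabet is None:
                raise InstanceError("write_solutions needs the alphabet")
            if fmt == "sdf":
                fh.write(solution_to_molblock(sol, alphabet))
                fh.write("$$$$\n")
            elif fmt == "lines":
                fh.write(
                    canonical.key_string(canonical.canonical_key(sol, alphabet))
                )
                fh.write("\n")
            else:
                raise InstanceError(f"unknown output format {fmt!r}")
            n += 1
    return n


# --------------------------------------------------------------------- fixtures
def synth_tree(
    seed: int | random.Random,
    alphabet: Alphabet,
    n_target: int,
    M_target: Optional[int] = None,
    max_tries: int = 5000,
) -> MultiTreeSolution:
    """A pseudo-random valence-exact multitree, reproducible from the seed.

    Samples a formula of ``n_target`` atoms with an even valence sum (and the
    requested multiplicity budget, if given), then a uniform labeled tree
    shape compatible with the valences; multiplicities are forced bottom-up
    and the draw is retried until they work out.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    from .oracle import _forced_multiplicities

    labs = list(alphabet.labels)
    tries = max_tries if n_target <= 12 else 200
    for _ in range(tries):
        labels = sorted(rng.choices(labs, k=n_target), key=alphabet.index)
        deg = sum(alphabet.valence[l] for l in labels)
        if deg % 2:
            continue
        M = deg // 2 - (n_target - 1)
        if M < 0 or (M_target is not None and M != M_target):
            continue
        caps = [alphabet.valence[l] - 1 for l in labels]
        if n_target == 1:
            continue  # a positive-valence atom alone has nonzero residual
        if n_target == 2:
            adj: list[list[int]] | None = [[1], [0]]
        else:
            seq = []
            ok = True
            left = list(caps)
            for _ in range(n_target - 2):
                pool = [v for v in range(n_target) if left[v] > 0]
                if not pool:
                    ok = False
                    break
                v = rng.choice(pool)
                left[v] -= 1
                seq.append(v)
            if not ok:
                continue
            import networkx as nx

            tree = nx.from_prufer_sequence(seq)
            adj = [list(tree.neighbors(v)) for v in range(n_target)]
        edges = _forced_multiplicities(n_target, labels, adj, alphabet)
        if edges is None:
            continue
        sol = MultiTreeSolution(tuple(labels), tuple(edges))
        sol.validate(alphabet)
        return sol
    # formula-first sampling rejects too often on large requests; fall back to
    # shape-first construction with labels matched to realized degrees
    sol = _synth_by_degree(rng, alphabet, n_target, M_target, max_tries)
    if sol is not None:
        return sol
    raise InstanceError("no feasible synthetic tree found for the request")


def _synth_by_degree(
    rng: random.Random,
    alphabet: Alphabet,
    n: int,
    M_target: Optional[int],
    max_tries: int,
) -> Optional[MultiTreeSolution]:
    """Random tree shape, optional extra bond units, labels by final degree."""
    import networkx as nx

    by_valence: dict[int, list[str]] = {}
    for lab in alphabet.labels:
        by_valence.setdefault(alphabet.valence[lab], []).append(lab)
    max_val = max(by_valence)
    if n < 2:
        return None
    for _ in range(max_tries):
        if n == 2:
            adj = {0: [1], 1: [0]}
            edges = [(0, 1)]
        else:
            seq = [rng.randrange(n) for _ in range(n - 2)]
            if any(seq.count(v) + 1 > max_val for v in set(seq)):
                continue
            g = nx.from_prufer_sequence(seq)
            adj = {v: list(g.neighbors(v)) for v in range(n)}
            edges = [tuple(sorted(e)) for e in g.edges()]
        mult = {e: 1 for e in edges}
        deg = {v: len(adj[v]) for v in range(n)}
        extra = M_target if M_target is not None else rng.choice((0, 0, 1, 1, 2))
        ok = True
        for _ in range(extra):
            room = [
                e for e in edges if deg[e[0]] < max_val and deg[e[1]] < max_val
            ]
            if not room:
                ok = False
                break
            e = rng.choice(room)
            mult[e] += 1
            deg[e[0]] += 1
            deg[e[1]] += 1
        if not ok:
            continue
        try:
            labels = tuple(rng.choice(by_valence[deg[v]]) for v in range(n))
        except KeyError:
            continue  # some degree has no matching valence in this alphabet
        sol = MultiTreeSolution(
            labels, tuple(sorted((u, v, mult[(u, v)]) for u, v in edges))
        )
        sol.validate(alphabet)
        return sol
    return None


def synth_instance(
    seed: int | random.Random,
    alphabet: Alphabet,
    n_target: int,
    K: int,
    w: int,
    M_target: Optional[int] = None,
) -> tuple[Instance, MultiTreeSolution]:
    """An instance guaranteed to admit at least one solution (the planted tree)."""
    tree = synth_tree(seed, alphabet, n_target, M_target)
    inst = make_instance(LoadedMolecule(tree, alphabet), K, w)
    return inst, tree


# ----------------------------------------------------------------- instance IO
def instance_to_dict(inst: Instance) -> dict:
    return {
        "alphabet": dict(inst.alphabet.valence),
        "order": list(inst.alphabet.labels),
        "K": inst.K,
        "g_L": {format_sequence_key(t): v for t, v in sorted(inst.g_l.items())},
        "g_U": {format_sequence_key(t): v for t, v in sorted(inst.g_u.items())},
        "g_U_default": "inf" if inst.upper_default is math.inf else 0,
    }


def save_instance(inst: Instance, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(instance_to_dict(inst), sort_keys=False))


def load_instance(path: str | Path) -> Instance:
    raw = yaml.safe_load(Path(path).read_text())
    return validate_instance(raw)
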
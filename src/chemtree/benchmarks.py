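"""The KEGG benchmark compounds used to exercise the full pipeline.

Structures are reconstructed from the accessions' known chemistry and are
built as MOL blocks at run time (no structure files ship with the package):

* ``C00062`` -- L-arginine (hydrogen-explicit: 26 vertices, no ring).
* ``C03343`` -- mono(2-ethylhexyl) phthalate, the phthalate-degradation
  monoester (42 atoms, one benzene ring: 37 vertices after contraction).
* ``C07178`` -- formula C21H28N2O5 with two isolated benzene rings; the
  concrete structure could not be pinned down, so this entry is a SYNTHETIC
  stand-in with the correct formula and ring count.  It exercises the
  preprocessing arithmetic (56 atoms - 2 x 5 = 46 vertices) but its feature
  vector is not that of the real compound.
* ``C03690`` -- bis(2-ethylhexyl) phthalate (66 atoms, one ring: 61
  vertices).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BenchmarkCompound", "BENCHMARKS", "molblock"]


@dataclass(frozen=True)
class BenchmarkCompound:
    accession: str
    name: str
    smiles: str
    n_contracted: int  # hydrogen-explicit vertex count after ring contraction
    benzene_rings: int
    synthetic: bool = False  # True: stand-in structure, formula/rings only


BENCHMARKS: dict[str, BenchmarkCompound] = {
    "C00062": BenchmarkCompound(
        "C00062", "L-arginine", "NC(=N)NCCCC(N)C(=O)O", 26, 0
    ),
    "C03343": BenchmarkCompound(
        "C03343",
        "mono(2-ethylhexyl) phthalate",
        "CCCCC(CC)COC(=O)c1ccccc1C(=O)O",
        37,
        1,
    ),
    "C07178": BenchmarkCompound(
        "C07178",
        "synthetic C21H28N2O5 stand-in (two benzene rings)",
        "COC(=O)NCCC(O)COc1ccccc1CNCCOc1ccccc1",
        46,
        2,
        synthetic=True,
    ),
    "C03690": BenchmarkCompound(
        "C03690",
        "bis(2-ethylhexyl) phthalate",
        "CCCCC(CC)COC(=O)c1ccccc1C(=O)OCC(CC)CCCC",
        61,
        1,
    ),
}


def molblock(accession: str) -> str:
    """MOL V2000 block of a benchmark compound (built via RDKit)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(BENCHMARKS[accession].smiles)
    return Chem.MolToMolBlock(mol)
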
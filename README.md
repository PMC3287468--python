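# chemtree

Exact, isomorph-free enumeration of **tree-like chemical multigraphs** whose
**path-frequency feature vector** lies between a given pair of lower and
upper bound vectors.

## The problem

Molecular descriptors based on labeled-path counts map a compound to a
feature vector: the entry of `f_K(G)` for a label sequence `t` (up to `K+1`
atom labels) counts the directed simple paths in `G` spelling `t`, with
parallel bonds collapsed.  Inverting that map — listing every molecule
consistent with a descriptor — is the *pre-image* problem behind
structure elucidation from spectra and kernel-based *de novo* design.
Because a single exact vector often has no chemical realization, the useful
formulation is a box constraint: given an atom alphabet Σ with valences
`val`, a level `K`, and bound vectors `g_L ≤ g_U` (with atom counts fixed,
`g_L(ℓ) = g_U(ℓ)`), find **all** Σ-labeled multitrees `T` — connected,
acyclic after collapsing parallel edges — with

```
g_L ≤ f_K(T) ≤ g_U      and      deg(v; T) = val(ℓ(v)) for every atom v,
```

each exactly once up to isomorphism.  `chemtree` implements a
branch-and-bound solver for this problem together with a brute-force
reference enumerator, molecule-file preprocessing, and a CLI.

## The algorithm

* **Canonical generation.**  Every free tree has a unique Jordan centroid (a
  vertex, or an edge for even `n`).  Solutions are built rooted at the
  centroid as *left-heavy* ordered trees — the plane embedding whose
  depth-label sequence is lexicographically maximal — by repeatedly
  appending a leaf on the rightmost path.  Each left-heavy tree arises from
  exactly one parent (remove its rightmost leaf), so the search space is a
  family tree visited without duplicates; bicentroid solutions are built as
  ordered pairs of `n/2`-vertex halves joined by a bridge.
* **Forced multiplicities.**  When a vertex leaves the rightmost path its
  remaining valence must be absorbed by its parent edge, so bond orders are
  never guessed: `Mul(v, parent) = val(ℓ(v)) − Σ` (closed child orders).
* **Pruning.**  A state dies as soon as (C1) the root can no longer be the
  centroid, (C2) a degree would exceed a valence or a forced order drops
  below 1, (C3) some entry of `f_K(T)` exceeds `g_U` (and, at full size,
  misses `g_L`), (C4) the unplaced atoms cannot be attached consistently
  with the pair bounds — a graph-*detachment* feasibility test over the
  label-contracted relaxation — or (C5) the fixed multiple-bond units exceed
  the budget `M = Σ_ℓ val(ℓ)·g(ℓ)/2 − (n−1)`.  Every cut is sound:
  disabling any subset changes the node count, never the emitted set.
* **Oracle.**  An independent brute-force enumerator (capped Prüfer
  sequences + forced bond orders + canonical-key dedup) provides ground
  truth on small instances; the test suite checks exact agreement.

Input molecules (MDL MOL/SDF) are preprocessed hydrogen-explicit, and
isolated benzene rings are contracted to a virtual atom of valence six so
that monocyclic aromatics become tree-like.  A realized vector `g` is turned
into an instance of width `w` by `g_U = a + w`, `g_L = max(0, a − w)` on its
positive entries (atom counts stay fixed).

## Worked example

Ethanol and dimethyl ether are the two realizations of C₂H₆O; their level-1
vectors differ, so a width-1 box around ethanol's vector keeps only ethanol:

```python
import chemtree as ct

inst = ct.validate_instance({
    "alphabet": {"C": 4, "O": 2, "H": 1},
    "order": ["C", "O", "H"],
    "K": 1,
    "g_L": {"C": 2, "O": 1, "H": 6},   # formula-only box (K=1, pairs free)
    "g_U": {"C": 2, "O": 1, "H": 6},
})
print("n =", inst.n, " M =", inst.M)
sols, report = ct.run(inst)
print("solutions:", report.solutions, " nodes visited:", report.nodes)
```

prints

```
n = 9  M = 0
solutions: 2  nodes visited: 91
```

— both C₂H₆O isomers (all bond orders forced single, `M = 0`).  The same
flow from a structure file, via the CLI:

```
$ chemtree extract-fv ethanol.mol -K 1
K: 1
n: 9
counts:
  C: 2
  C-C: 2
  C-H: 5
  C-O: 1
  ...
$ chemtree make-instance ethanol.mol -K 1 -w 1 --out inst.yaml
{"n": 9, "M": 0, "K": 1}
$ chemtree enumerate --instance inst.yaml --count-only
{"solutions": 1, "nodes": 113, "prunes": {"valence": 204, "multiplicity": 14,
 "detachment": 7, "leftheavy": 34, "centroid": 15, "feature": 1, "final": 1},
 "elapsed_s": 0.016, "disabled_cuts": []}
```

The width-1 box around ethanol's level-1 vector excludes dimethyl ether
(its lower bound demands a C–C path that the ether lacks), so exactly one
structure survives.  `chemtree oracle` runs the brute-force reference and
`chemtree compare` diffs the two solution sets.

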
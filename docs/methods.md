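# Methods

## Model

A chemical compound is modelled as a `(Σ, val)`-labeled multitree: a
connected multigraph without self-loops, acyclic once parallel edges are
collapsed, in which every vertex's multiplicity-counted degree equals the
valence of its label.  The feature vector `f_K(T)` counts directed simple
paths of at most `K` edges by their label sequences over the collapsed
simple tree; a path and its reverse count separately, so every realized
vector satisfies `#t = #reverse(t)`, and the length-1 entries are the
molecular formula.  An instance consists of Σ, `val`, `K` and bounds
`g_L ≤ g_U` with equal length-1 entries; the target set is every multitree
with `g_L ≤ f_K(T) ≤ g_U`, listed once per isomorphism class.

Two derived constants drive the search: the vertex count
`n = Σ_ℓ g(ℓ)` and the multiplicity budget
`M = Σ_ℓ val(ℓ)·g(ℓ)/2 − (n−1)`, the exact number of extra bond units
(double/triple-bond increments) every solution must spend.

## Canonical generation

Rooted trees are compared by their depth-label sequences, the DFS-ordered
`(depth, label)` pairs.  The pair order makes a deeper pair larger and, at
equal depth, a label earlier in the alphabet's declared order larger;
sequences compare lexicographically with a strict prefix smaller.  The
left-heavy embedding — every vertex's child subtrees in non-increasing
sequence order — is the unique maximal embedding of a rooted tree's class.
The declared label order is arbitrary: permuting it permutes traversal
order, and the tests verify the emitted solution sets are identical.

Generation appends one leaf at a time at a rightmost-path position.  The
incremental left-heaviness check re-compares, for each ancestor of the new
leaf, its last two child subtrees (lazily, with early exit): these are
exactly the sibling comparisons the append can break.  The parent of a
state is obtained by removing its rightmost leaf, so each left-heavy tree is
reached exactly once; this is verified against exhaustive plane-tree
generation filtered by the standalone left-heavy test.

Unicentroid solutions are generated rooted at the centroid and the final
tree's centroid is re-verified exactly at emission; the intermediate
centroid cut only applies Jordan's bound (no root child subtree may exceed
`⌊(n−1)/2⌋` vertices), which is conservative but never aggressive.
Bicentroid solutions (even `n`) are built as an ordered pair: the first
half is completed and closed, then the second half grows *attached through
the open bridge*, so the feature counts always refer to the joined tree and
cross-bridge paths prune normally.  The bridge order is forced by both
roots' residual valences and must agree.  Duplicate pairs are avoided by
requiring the first half's depth-label sequence to be at least the
second's, enforced prefix-wise during growth.  The detachment cut is not
applied during second-half growth (its construction presumes the
unicentroid rightmost-path layout); all other cuts are, and the soundness
suite covers both modes.

## Forced multiplicities and closing

Bond orders are never searched over.  While a vertex sits on the rightmost
path its parent edge is open; when an append at a shallower position
removes it from the path, its parent-edge order is forced to
`val − Σ(closed child orders)`, applied deepest-first.  Any forced order
below 1, or any vertex whose closed orders plus reserved open edges exceed
its valence, kills the branch.  At full size the remaining rightmost-path
edges close the same way and the root must land exactly on its valence.
The running total `M(T) = Σ(m_e − 1)` over closed edges is maintained
incrementally and checked against the budget `M`.

## Pruning operations

* **Valence** — folded into the append/closing mechanics above.
* **Feature-vector** — appending leaf `u` creates exactly the directed
  paths with endpoint `u`; only the touched entries are re-checked against
  `g_U` (a per-entry dictionary with a configurable default: unbounded for
  hand-written instances, zero for instances widened from a realized
  vector, where an unseen sequence really is forbidden; sequences beyond
  level `K+1` are never constrained).  The lower condition `g_L ≤ f_K(T)`
  is only decidable at full size and is checked there, together with a full
  upper check so that disabling the cut cannot change the emitted set.
* **Multiplicity** — prune when `M(T) > M`.
* **Detachment** — see below.

Cut order per node is cheapest-first (valence/feature inside the append,
then multiplicity, centroid, detachment); order cannot affect the solution
set.  All cuts are toggleable (`CutConfig`), and the acceptance suite
verifies on 200 synthetic instances that disabling any one of them leaves
the solution set untouched.

## Detachment feasibility

An `r`-detachment splits each vertex `v` of a multigraph into `r(v)` copies
and reroutes each edge to one copy per endpoint; a degree specification
`ρ` prescribes each copy's degree (summing to `deg(v)`, loops counted
twice).  `detachment_feasible` decides existence of a *connected, loopless*
ρ-detachment by checking: every copy degree is at least 1 (when more than
one copy exists overall); the loops at each `v` can be spread over distinct
copies (`Σ_j min(ρ_j(v), L) ≥ 2L` for `L` loops); the loop-free skeleton is
connected; and the subset condition
`r(X) + c(G − X) − d(X, V; G) ≤ 1` for every nonempty `X ⊆ V`, where `d`
counts edge units with an endpoint in `X` (a loop once) and `c` counts
components including isolated vertices.  These conventions were fixed by
requiring exact agreement with an explicit witness search
(`brute_force_detachment`) over an exhaustive sweep of ~500 000 small
problems (≤ 4 vertices, ≤ 6 edge units, `Σr ≤ 8`); the acceptance suite
re-runs a deterministic sub-sweep of that envelope (> 10 000 problems,
thinned degree specifications at the largest sizes) to keep the default
test run inside a sensible wall-clock budget.

The *cut* built on this test aggregates the future of a search state: one
vertex per label still to be placed (split count = remaining atoms), plus
one vertex for the open rightmost path (split count 1).  Edge capacities
are the level-1 pair allowances of `g_U` minus the bonds already present
(diagonal entries halved: `#ℓℓ` counts both traversals of an `ℓ–ℓ` bond),
clamped at zero; capacities toward the rightmost-path vertex are further
capped by the path's residual valence after reserving one unit per open
edge.  Two conditions prune: (a) the total remaining lower-bound demand
`Σ ĝ_L` exceeds `n − |T|`, the number of bonds any completion can still
create; (b) the subset condition fails on the upper relaxation.  Both err
on the generous side wherever the aggregation loses information (shared
pair allowances are counted once per use site), so the cut can only fail to
prune, never lose a solution — the property the soundness tests enforce.
ρ-compatibility is deliberately not part of the cut: the subset condition
alone is monotone under adding capacity, which is what makes the
relaxation safe.

## Brute-force oracle

The reference enumerator generates every labeled tree shape on the fixed
atom multiset from Prüfer sequences (a vertex of valence `val` appears at
most `val − 1` times, so hydrogens never appear and the space collapses to
the heavy-atom arrangements), forces bond orders bottom-up, discards
infeasible shapes, deduplicates by canonical key and filters by the feature
box.  It is capped at 9 vertices and kept deliberately naive; its only
job is to be obviously exhaustive.

## Canonical key

Solutions are identified by a nested-tuple normal form: root at the
centroid, represent each subtree as `(label, parent-edge order, sorted
child forms)`, and for a bicentroid take the ordered pair of half forms
plus the bridge order.  Keys are equal exactly for isomorphic multitrees
(verified against exhaustive bijection search on small cases) and have a
stable string form used in `lines` output.

## Synthetic data

`synth_tree` draws a random valence-exact multitree: it samples a formula
with an even valence sum and a compatible Prüfer-encoded shape, forcing
bond orders bottom-up and retrying until consistent; for requests beyond
~12 vertices it switches to shape-first sampling, drawing a random tree,
sprinkling extra bond units (0–2 unless a budget is requested) and
assigning each vertex a label whose valence matches its realized degree.
`synth_instance` widens the planted tree's own vector, so every generated
instance provably admits at least one solution — the basis of the
planted-recovery tests.  The generator emulates the combinatorial
structure of the problem (labels, valences, bond orders, widths `w` 0–3,
levels `K` 0–4, up to 8 atoms where the oracle is exact); it does not
emulate chemical realism beyond valence arithmetic — no electronegativity,
ring systems or stereochemistry — so passing tests certify combinatorial
correctness, not chemical plausibility, of real-world predictions.

## Benchmarks

Four KEGG compounds exercise the full pipeline at realistic size.  Their
structures are reconstructed from the accessions' known chemistry and built
from SMILES at run time: C00062 (L-arginine), C03343 (mono(2-ethylhexyl)
phthalate) and C03690 (bis(2-ethylhexyl) phthalate); C07178 could not be
identified with confidence and ships as a clearly labelled synthetic
stand-in of formula C21H28N2O5 with two isolated benzene rings, used only
for the preprocessing vertex-count identity.  Preprocessing is
hydrogen-explicit and contracts each isolated plain benzene ring to a
virtual atom of valence six that keeps the ring hydrogens (the only
assignment consistent with valence 6), giving 26/37/46/61 vertices.  The
reproduced enumeration settings — C00062 at `(K,w) = (4,1), (3,1), (2,0)`
and C03343 at `(2,0)` — were chosen as the largest instances an
interpreted implementation completes in a couple of minutes each
(search trees of order 10^5 nodes); larger settings of the same instances
grow toward 10^6–10^8 nodes and are out of scope for the default suite.

## Numerical and degenerate-input choices

* Bounds are symmetrized at validation (`g_U`: min of the two
  orientations; `g_L`: max), justified by `#t = #reverse(t)` on every
  realized vector; user bounds violating realizability simply yield empty
  enumerations rather than errors.
* Missing `g_U` entries default to unbounded in hand-written instance
  files and to 0 in widened instances; missing `g_L` entries are 0.
* A single-atom instance (`n = 1`) has no solution for any positive
  valence and enumerates to the empty stream.
* Odd valence sums and negative budgets are rejected at validation with
  distinct errors.
* Fused or hetero-substituted aromatic rings are a hard preprocessing
  error, never a silent guess; bond orders above 3 cannot be written to
  MOL V2000 and raise.

## Known limitations

Visited-node counts and wall-clock are implementation-defined and not a
correctness surface; the detachment cut here is a reconstruction guarded by
soundness rather than a transcription, so its pruning power may differ
from other implementations.  Output order is deterministic (DFS order of
the canonical search) but carries no semantic meaning.  Performance is
roughly 2–4 k nodes/s on one CPU at benchmark sizes.
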
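import itertools
import random

import pytest

import chemtree as ct
from chemtree.canonical import (
    Centroid,
    DepthLabelSequence,
    RootedTree,
    canonical_key,
    compare_sequences,
    depth_label_sequence,
    find_centroid,
    is_left_heavy,
)
from chemtree.chem_model import Alphabet, MultiTreeSolution

AB = Alphabet(("a", "b"), {"a": 4, "b": 4})


def seq(*pairs):
    return DepthLabelSequence(tuple(pairs))


class TestDepthLabelSequence:
    def test_single_vertex(self):
        t = RootedTree(["a"], [[]])
        assert depth_label_sequence(t).items == ((0, "a"),)

    def test_root_with_two_children(self):
        t = RootedTree(["a", "b", "a"], [[1, 2], [], []])
        assert depth_label_sequence(t).items == ((0, "a"), (1, "b"), (1, "a"))

    def test_chain(self):
        t = RootedTree(["a", "b", "a"], [[1], [2], []])
        assert depth_label_sequence(t).items == ((0, "a"), (1, "b"), (2, "a"))


class TestCompareSequences:
    def test_equal(self):
        s = seq((0, "a"), (1, "a"))
        assert compare_sequences(s, s, AB) == 0

    def test_deeper_is_larger(self):
        deep = seq((0, "a"), (1, "a"), (2, "a"))
        wide = seq((0, "a"), (1, "a"), (1, "a"))
        assert compare_sequences(deep, wide, AB) == 1

    def test_prefix_is_smaller(self):
        short = seq((0, "a"), (1, "a"))
        longer = seq((0, "a"), (1, "a"), (1, "b"))
        assert compare_sequences(short, longer, AB) == -1

    def test_earlier_label_is_larger(self):
        sa = seq((0, "a"), (1, "a"))
        sb = seq((0, "a"), (1, "b"))
        assert compare_sequences(sa, sb, AB) == 1


def all_embeddings(tree: RootedTree):
    """Every plane embedding obtained by permuting each child list."""
    perms_per_vertex = [
        list(itertools.permutations(ch)) for ch in tree.children
    ]
    for combo in itertools.product(*perms_per_vertex):
        yield RootedTree(tree.labels, [list(c) for c in combo], tree.root)


class TestLeftHeavy:
    def test_any_path_is_left_heavy(self):
        t = RootedTree(["a", "a", "b"], [[1], [2], []])
        assert is_left_heavy(t, AB)

    def test_short_subtree_before_long_is_not(self):
        # root with a single-vertex child before a 2-chain child
        t = RootedTree(["a", "a", "a", "a"], [[1, 2], [], [3], []])
        assert not is_left_heavy(t, AB)
        mirror = RootedTree(["a", "a", "a", "a"], [[2, 1], [], [3], []])
        assert is_left_heavy(mirror, AB)

    @pytest.mark.parametrize("seed", range(20))
    def test_left_heavy_iff_maximal_sequence(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 7)
        labels = [rng.choice("ab") for _ in range(n)]
        parents = [-1] + [rng.randrange(i) for i in range(1, n)]
        tree = RootedTree.from_parents(labels, parents)
        embeddings = list(all_embeddings(tree))
        best = max(
            embeddings,
            key=lambda e: tuple(
                (d, AB.size - AB.index(l)) for d, l in depth_label_sequence(e).items
            ),
        )
        best_seq = depth_label_sequence(best)
        for e in embeddings:
            lh = is_left_heavy(e, AB)
            is_max = compare_sequences(depth_label_sequence(e), best_seq, AB) == 0
            assert lh == is_max

    def test_exactly_one_left_heavy_embedding_per_tree(self):
        rng = random.Random(5)
        for _ in range(10):
            n = rng.randint(2, 7)
            labels = [rng.choice("ab") for _ in range(n)]
            parents = [-1] + [rng.randrange(i) for i in range(1, n)]
            tree = RootedTree.from_parents(labels, parents)
            seqs = {
                depth_label_sequence(e).items
                for e in all_embeddings(tree)
                if is_left_heavy(e, AB)
            }
            assert len(seqs) == 1


def centroid_by_definition(tree: MultiTreeSolution) -> Centroid:
    """O(n^2) re-check of Jordan's characterization."""
    n = tree.n
    adj = tree.adjacency()

    def comp_sizes(removed_v=None, removed_e=None):
        seen = set()
        sizes = []
        for start in range(n):
            if start == removed_v or start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                v = stack.pop()
                for w in adj[v]:
                    if w == removed_v or w in comp:
                        continue
                    if removed_e and {v, w} == set(removed_e):
                        continue
                    comp.add(w)
                    stack.append(w)
            seen |= comp
            sizes.append(len(comp))
        return sizes

    half = (n - 1) // 2
    for v in range(n):
        if n == 1 or max(comp_sizes(removed_v=v)) <= half:
            return Centroid("unicentroid", (v,))
    for a, b, _ in tree.edges:
        if comp_sizes(removed_e=(a, b)) == [n // 2, n // 2]:
            return Centroid("bicentroid", (min(a, b), max(a, b)))
    raise AssertionError


class TestCentroid:
    def test_path5_middle_vertex(self):
        t = MultiTreeSolution(
            ("a",) * 5, tuple((i, i + 1, 1) for i in range(4))
        )
        assert find_centroid(t) == Centroid("unicentroid", (2,))

    def test_path4_middle_edge(self):
        t = MultiTreeSolution(("a",) * 4, tuple((i, i + 1, 1) for i in range(3)))
        assert find_centroid(t) == Centroid("bicentroid", (1, 2))

    def test_star_hub(self):
        t = MultiTreeSolution(("a", "b", "b", "b"), ((0, 1, 1), (0, 2, 1), (0, 3, 1)))
        assert find_centroid(t) == Centroid("unicentroid", (0,))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_definition_on_random_trees(self, seed, cnoh_alphabet):
        rng = random.Random(seed)
        tree = ct.synth_tree(rng, cnoh_alphabet, rng.randint(2, 40))
        assert find_centroid(tree) == centroid_by_definition(tree)


def isomorphic_brute(a: MultiTreeSolution, b: MultiTreeSolution) -> bool:
    if sorted(a.vertices) != sorted(b.vertices) or len(a.edges) != len(b.edges):
        return False
    eb = {(min(u, v), max(u, v)): m for u, v, m in b.edges}
    for perm in itertools.permutations(range(b.n)):
        if any(a.vertices[i] != b.vertices[perm[i]] for i in range(a.n)):
            continue
        ok = all(
            eb.get((min(perm[u], perm[v]), max(perm[u], perm[v]))) == m
            for u, v, m in a.edges
        )
        if ok:
            return True
    return False


class TestCanonicalKey:
    def test_reindexing_invariance(self, cho_alphabet):
        ethanol = MultiTreeSolution(
            ("C", "C", "O", "H", "H", "H", "H", "H", "H"),
            ((0, 1, 1), (1, 2, 1), (0, 3, 1), (0, 4, 1), (0, 5, 1),
             (1, 6, 1), (1, 7, 1), (2, 8, 1)),
        )
        # same molecule, different vertex numbering (O first)
        ethanol2 = MultiTreeSolution(
            ("O", "C", "C", "H", "H", "H", "H", "H", "H"),
            ((0, 1, 1), (1, 2, 1), (0, 3, 1), (1, 4, 1), (1, 5, 1),
             (2, 6, 1), (2, 7, 1), (2, 8, 1)),
        )
        assert canonical_key(ethanol, cho_alphabet) == canonical_key(
            ethanol2, cho_alphabet
        )

    def test_constitutional_isomers_differ(self, cho_alphabet):
        ethanol = MultiTreeSolution(
            ("C", "C", "O", "H", "H", "H", "H", "H", "H"),
            ((0, 1, 1), (1, 2, 1), (0, 3, 1), (0, 4, 1), (0, 5, 1),
             (1, 6, 1), (1, 7, 1), (2, 8, 1)),
        )
        dme = MultiTreeSolution(
            ("C", "O", "C", "H", "H", "H", "H", "H", "H"),
            ((0, 1, 1), (1, 2, 1), (0, 3, 1), (0, 4, 1), (0, 5, 1),
             (2, 6, 1), (2, 7, 1), (2, 8, 1)),
        )
        assert canonical_key(ethanol, cho_alphabet) != canonical_key(dme, cho_alphabet)

    @pytest.mark.parametrize("seed", range(15))
    def test_key_equality_iff_isomorphism(self, seed, cho_alphabet):
        rng = random.Random(seed)
        a = ct.synth_tree(rng, cho_alphabet, rng.randint(2, 7))
        if seed % 2:
            # a scrambled copy of a: keys must collide
            perm = list(range(a.n))
            rng.shuffle(perm)
            b = MultiTreeSolution(
                tuple(a.vertices[perm.index(i)] for i in range(a.n)),
                tuple(
                    sorted(
                        (min(perm[u], perm[v]), max(perm[u], perm[v]), m)
                        for u, v, m in a.edges
                    )
                ),
            )
        else:
            b = ct.synth_tree(rng, cho_alphabet, rng.randint(2, 7))
        same_key = canonical_key(a, cho_alphabet) == canonical_key(b, cho_alphabet)
        assert same_key == isomorphic_brute(a, b)

    def test_key_string_stable(self, cho_alphabet):
        t = ct.synth_tree(1, cho_alphabet, 6)
        k1 = ct.key_string(canonical_key(t, cho_alphabet))
        k2 = ct.key_string(canonical_key(t, cho_alphabet))
        assert k1 == k2 and isinstance(k1, str)
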
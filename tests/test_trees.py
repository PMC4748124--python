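"""Distances, neighbor-joining, Dollo losses, Robinson-Foulds."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from intronarch.homology import KEY_COLUMNS, PresenceMatrix
from intronarch.trees import (
    distance_matrix,
    dollo_losses,
    intron_distance,
    neighbor_joining,
    robinson_foulds,
    root_on_outgroup,
    total_dollo_losses,
)

from conftest import dollo_by_subset_search


def presence_matrix(rows, species):
    index = pd.MultiIndex.from_tuples(
        [(f"og{i}", i, 0) for i in range(len(rows))], names=KEY_COLUMNS
    )
    return PresenceMatrix(
        presence=pd.DataFrame(rows, index=index, columns=species, dtype=np.int8),
        lengths=pd.DataFrame(columns=KEY_COLUMNS + ["species", "genomic_length"]),
    )


def random_tree(rng, n_taxa, min_bl=0.05, max_bl=1.0):
    """A random binary tree built by sequential joins."""
    ns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    nodes = []
    for t in ns:
        node = dendropy.Node()
        node.taxon = t
        node.edge.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(min_bl, max_bl))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for n in nodes:
        root.add_child(n)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def path_length_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((t.label for t in tree.taxon_namespace))
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for a, b in itertools.combinations(taxa, 2):
        d = pdm.patristic_distance(
            tree.taxon_namespace.get_taxon(a), tree.taxon_namespace.get_taxon(b)
        )
        D.at[a, b] = D.at[b, a] = d
    return D


class TestIntronDistance:
    def test_identical_sets_zero(self):
        m = presence_matrix([[1, 1], [1, 1], [0, 0]], ["a", "b"])
        assert intron_distance(m, "a", "b") == 0.0

    def test_disjoint_sets_one(self):
        m = presence_matrix([[1, 0], [0, 1]], ["a", "b"])
        assert intron_distance(m, "a", "b") == 1.0

    def test_jaccard_count_case(self):
        # |A ∩ B| = 1, |A ∪ B| = 4
        m = presence_matrix([[1, 1], [1, 0], [1, 0], [0, 1]], ["a", "b"])
        assert intron_distance(m, "a", "b") == pytest.approx(0.75)

    def test_metric_axioms_on_random_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            rows = rng.integers(0, 2, size=(60, 4))
            rows[0] = 1  # avoid all-empty species
            m = presence_matrix(rows.tolist(), ["a", "b", "c", "d"])
            D = distance_matrix(m)
            assert np.allclose(D.values, D.values.T)
            assert np.all(np.diag(D.values) == 0)
            for x, y, z in itertools.permutations(D.index, 3):
                assert D.at[x, z] <= D.at[x, y] + D.at[y, z] + 1e-12


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tree = neighbor_joining(D)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        rng = np.random.default_rng(4)
        source = random_tree(rng, 5)
        D = path_length_matrix(source)
        tree = neighbor_joining(D)
        assert robinson_foulds(tree, source) == 0
        got = path_length_matrix(tree)
        assert np.allclose(got.values, D.loc[got.index, got.columns].values, atol=1e-9)

    def test_tie_handling_is_permutation_invariant(self):
        # equidistant taxa: every Q is tied
        taxa = list("abcd")
        D = pd.DataFrame(1.0, index=taxa, columns=taxa)
        np.fill_diagonal(D.values, 0.0)
        base = neighbor_joining(D).as_string(schema="newick")
        for perm in itertools.permutations(taxa):
            Dp = D.loc[list(perm), list(perm)]
            assert neighbor_joining(Dp).as_string(schema="newick") == base

    def test_small_or_asymmetric_input_rejected(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            neighbor_joining(D)
        bad = pd.DataFrame(
            [[0, 1, 2], [9, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc")
        )
        with pytest.raises(ValueError):
            neighbor_joining(bad)

    def test_agrees_with_skbio_on_random_distances(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(8)
        tree_src = random_tree(rng, 7)
        D = path_length_matrix(tree_src)
        noise = rng.uniform(0, 0.01, size=D.shape)
        D = D + noise + noise.T  # perturb but keep symmetric
        np.fill_diagonal(D.values, 0.0)
        mine = neighbor_joining(D)
        sk = sk_nj(SkDM(D.values, ids=list(D.index)))
        sk_tree = dendropy.Tree.get(data=str(sk), schema="newick")
        assert robinson_foulds(mine, sk_tree) == 0


class TestDollo:
    def make_tree(self, newick):
        t = dendropy.Tree.get(data=newick, schema="newick")
        t.is_rooted = True
        return t

    def test_present_everywhere_no_losses(self):
        t = self.make_tree("((a,b),(c,d));")
        assert dollo_losses(t, {sp: 1 for sp in "abcd"}) == 0

    def test_two_sister_leaves_gain_at_mrca(self):
        t = self.make_tree("((a,b),(c,d));")
        assert dollo_losses(t, {"a": 1, "b": 1}) == 0

    def test_caterpillar_scattered_presence(self):
        t = self.make_tree("(((((t1,t2),t3),t4),t5),t6);")
        # present at t2 and t4: MRCA covers t1..t4; absent subtrees {t1},{t3}
        assert dollo_losses(t, {"t2": 1, "t4": 1}) == 2

    def test_matches_exhaustive_subset_search(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            t = random_tree(rng, 6)
            leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
            for bits in itertools.product([0, 1], repeat=6):
                present = {sp for sp, b in zip(leaves, bits) if b}
                if not present:
                    continue
                got = dollo_losses(t, {sp: 1 for sp in present})
                assert got == dollo_by_subset_search(t, present)

    def test_total_losses_invariant_to_character_order(self):
        t = self.make_tree("((a,b),(c,d));")
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 2, size=(50, 4))
        rows[rows.sum(axis=1) == 0, 0] = 1
        m = presence_matrix(rows.tolist(), list("abcd"))
        shuffled = PresenceMatrix(
            presence=m.presence.sample(frac=1, random_state=7), lengths=m.lengths
        )
        assert total_dollo_losses(t, m) == total_dollo_losses(t, shuffled)
        # and agrees with per-character summation
        per_char = sum(
            dollo_losses(t, row.to_dict()) for _, row in m.presence.iterrows()
        )
        assert total_dollo_losses(t, m) == per_char

    def test_unknown_taxon_rejected(self):
        t = self.make_tree("((a,b),(c,d));")
        with pytest.raises(KeyError):
            dollo_losses(t, {"zz": 1})


class TestRobinsonFoulds:
    def test_identical_topologies(self):
        t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        t2 = dendropy.Tree.get(data="((b,a),(d,c));", schema="newick")
        assert robinson_foulds(t1, t2) == 0

    def test_conflicting_quartets(self):
        t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        t2 = dendropy.Tree.get(data="((a,c),(b,d));", schema="newick")
        assert robinson_foulds(t1, t2) == 2

    def test_star_vs_resolved(self):
        star = dendropy.Tree.get(data="(a,b,c,d);", schema="newick")
        res = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        assert robinson_foulds(star, res) == 1

    def test_leaf_mismatch_rejected(self):
        t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        t2 = dendropy.Tree.get(data="((a,b),(c,e));", schema="newick")
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)


def test_root_on_outgroup_keeps_topology():
    D = pd.DataFrame(
        [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
        index=list("abcd"), columns=list("abcd"), dtype=float,
    )
    tree = neighbor_joining(D)
    rooted = root_on_outgroup(tree, ["c", "d"])
    assert rooted.is_rooted
    assert robinson_foulds(rooted, tree) == 0
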
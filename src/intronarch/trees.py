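"""Presence/absence phylogenetics: distances, neighbor-joining, Dollo.

Species are compared by their sets of homologized intron positions
(Jaccard distance by default, Dice available) and a tree is built with
canonical Saitou–Nei neighbor-joining.  Under Dollo parsimony each
intron position is gained once — at the most recent common ancestor of
the species carrying it — and explained below that node by a minimal
set of loss edges.

Trees are DendroPy objects throughout; the NJ agglomeration itself is
implemented here because its determinism contract (lexicographic
tie-break on taxon pairs, zero-clamped negative branches) is part of
this package's interface.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .homology import PresenceMatrix

__all__ = [
    "intron_distance",
    "distance_matrix",
    "neighbor_joining",
    "dollo_losses",
    "total_dollo_losses",
    "robinson_foulds",
    "root_on_outgroup",
]


def _presence_sets(matrix: PresenceMatrix) -> dict[str, set]:
    pres = matrix.presence
    return {
        sp: set(pres.index[pres[sp] == 1]) for sp in pres.columns
    }


def intron_distance(
    matrix: PresenceMatrix, a: str, b: str, method: str = "jaccard"
) -> float:
    """Distance in [0, 1] between two species' intron-position sets."""
    pres = matrix.presence
    va = pres[a].to_numpy(dtype=bool)
    vb = pres[b].to_numpy(dtype=bool)
    return _set_distance(va, vb, method)


def _set_distance(va: np.ndarray, vb: np.ndarray, method: str) -> float:
    inter = int((va & vb).sum())
    if method == "jaccard":
        union = int((va | vb).sum())
        return 1.0 - inter / union if union else 0.0
    if method == "dice":
        tot = int(va.sum()) + int(vb.sum())
        return 1.0 - 2.0 * inter / tot if tot else 0.0
    raise ValueError(f"unknown distance method {method!r}")


def distance_matrix(
    matrix: PresenceMatrix, method: str = "jaccard", restrict_shared_groups: bool = False
) -> pd.DataFrame:
    """Symmetric pairwise species distance matrix.

    With ``restrict_shared_groups`` (for non-universal group sets) each
    pair is compared only over groups in which both species carry at
    least one intron position; with universal single-copy groups the
    flag is a no-op.
    """
    pres = matrix.presence
    species = list(pres.columns)
    P = pres.to_numpy(dtype=bool)
    groups = pres.index.get_level_values("group_id")
    D = np.zeros((len(species), len(species)))
    for i, j in itertools.combinations(range(len(species)), 2):
        va, vb = P[:, i], P[:, j]
        if restrict_shared_groups:
            ga = set(groups[va])
            gb = set(groups[vb])
            shared = ga & gb
            if not shared:
                raise ValueError(
                    f"no shared analyzable groups for {species[i]} and {species[j]}"
                )
            keep = groups.isin(shared)
            va, vb = va[keep], vb[keep]
        D[i, j] = D[j, i] = _set_distance(va, vb, method)
    return pd.DataFrame(D, index=species, columns=species)


def neighbor_joining(D: pd.DataFrame) -> dendropy.Tree:
    """Canonical Saitou–Nei neighbor-joining.

    Requires a symmetric matrix over >= 3 taxa.  Ties in the Q
    criterion break on the lexicographically smallest (sorted) taxon
    pair, where an internal node is keyed by its smallest descendant
    leaf; the output is therefore invariant to row permutation.
    Negative branch lengths are clamped to zero with a warning.  The
    result is an unrooted tree (trifurcation at the final join).
    """
    taxa = list(D.index)
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.allclose(D.to_numpy(), D.to_numpy().T):
        raise ValueError("distance matrix is not symmetric")

    # canonical ordering for determinism under input permutation
    order = sorted(taxa)
    d = {a: {b: float(D.at[a, b]) for b in order} for a in order}

    ns = dendropy.TaxonNamespace(order)
    nodes: dict[str, dendropy.Node] = {}
    for t in order:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        nodes[t] = node

    def clamp(x: float) -> float:
        if x < -1e-12:
            warnings.warn(f"negative NJ branch length {x:.3g} clamped to 0")
        return max(x, 0.0)

    active = list(order)  # keys, kept sorted
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):  # active sorted -> pairs sorted
            q = (n - 2) * d[a][b] - r[a] - r[b]
            if best is None or q < best[0] - 1e-15:
                best = (q, a, b)
        _, a, b = best
        la = clamp(0.5 * d[a][b] + (r[a] - r[b]) / (2 * (n - 2)))
        lb = clamp(d[a][b] - 0.5 * d[a][b] - (r[a] - r[b]) / (2 * (n - 2)))
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.edge.length, nb.edge.length = la, lb
        parent.add_child(na)
        parent.add_child(nb)
        key = min(a, b)
        new_d = {
            c: 0.5 * (d[a][c] + d[b][c] - d[a][b]) for c in active if c not in (a, b)
        }
        for c, v in new_d.items():
            d[c][key] = v
        d[key] = new_d
        d[key][key] = 0.0
        nodes[key] = parent
        active = sorted(set(active) - {a, b} | {key})

    a, b, c = active
    root = dendropy.Node()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        nx = nodes[x]
        nx.edge.length = clamp(0.5 * (d[x][y] + d[x][z] - d[y][z]))
        root.add_child(nx)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson–Foulds distance (bipartition symmetric difference)."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    ns = dendropy.TaxonNamespace(sorted(l1))
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns)
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def _leaf_masks(tree: dendropy.Tree, leaf_order: Sequence[str]) -> dict:
    """Per-node bitmask of descendant leaves, postorder-computed."""
    idx = {name: i for i, name in enumerate(leaf_order)}
    masks = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = 1 << idx[node.taxon.label]
        else:
            m = 0
            for ch in node.child_nodes():
                m |= masks[ch]
            masks[node] = m
    return masks


def dollo_losses(tree: dendropy.Tree, presence: Mapping[str, int]) -> int:
    """Minimal loss count under Dollo parsimony for one character.

    The gain sits at the MRCA of the present taxa; losses are the
    maximal all-absent subtrees below it.
    """
    present = {sp for sp, v in presence.items() if v}
    if not present:
        raise ValueError("empty presence vector")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = present - leaves
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    leaf_order = sorted(leaves)
    masks = _leaf_masks(tree, leaf_order)
    idx = {name: i for i, name in enumerate(leaf_order)}
    p_mask = 0
    for sp in present:
        p_mask |= 1 << idx[sp]
    # MRCA: smallest-cardinality node whose leaf set covers all present taxa
    mrca = min(
        (n for n, m in masks.items() if m & p_mask == p_mask),
        key=lambda n: bin(masks[n]).count("1"),
    )
    losses = 0
    stack = [mrca]
    while stack:
        node = stack.pop()
        for ch in node.child_nodes():
            if masks[ch] & p_mask:
                stack.append(ch)
            else:
                losses += 1
    return losses


def total_dollo_losses(tree: dendropy.Tree, matrix: PresenceMatrix) -> int:
    """Sum of Dollo loss counts over all characters of a presence matrix."""
    pres = matrix.presence
    leaf_order = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    masks = _leaf_masks(tree, leaf_order)
    nodes = list(tree.postorder_node_iter())
    P = pres[leaf_order].to_numpy(dtype=np.uint64)
    bits = (P << np.arange(len(leaf_order), dtype=np.uint64)).sum(axis=1)
    total = 0
    cache: dict[int, int] = {}
    for pm in bits.tolist():
        n = cache.get(pm)
        if n is None:
            mrca = min(
                (nd for nd in nodes if masks[nd] & pm == pm),
                key=lambda nd: bin(masks[nd]).count("1"),
            )
            n = 0
            stack = [mrca]
            while stack:
                nd = stack.pop()
                for ch in nd.child_nodes():
                    if masks[ch] & pm:
                        stack.append(ch)
                    else:
                        n += 1
            cache[pm] = n
        total += n
    return total


def root_on_outgroup(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    """Root an unrooted tree on the edge above the given outgroup taxa.

    For display only: the NJ tree is unrooted by nature.  When the
    outgroup is not monophyletic in the unrooted tree, roots on the
    first outgroup taxon's edge.
    """
    tree = tree.clone(depth=1)
    taxa = [tree.taxon_namespace.get_taxon(t) for t in outgroup]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        mrca = tree.mrca(taxa=taxa)
    if mrca is tree.seed_node:
        mrca = tree.find_node_with_taxon_label(outgroup[0])
    edge = mrca.edge
    half = (edge.length or 0.0) / 2
    tree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    tree.is_rooted = True
    return tree
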
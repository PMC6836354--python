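from __future__ import annotations

import numpy as np
import pytest

from cmsscan.phylo import (
    DistanceMatrix,
    PhyloError,
    neighbor_joining,
    pairwise_distances,
    parse_newick,
)
from ._oracles import tree_path_distances


def test_identical_sequences_zero_matrix():
    dm = pairwise_distances({"a": "MKLV" * 10, "b": "MKLV" * 10, "c": "MKLV" * 10})
    assert np.all(dm.distances == 0)


def test_p_distance_counts_differing_columns(rng):
    aas = list("ARNDCEQGHILKMFPSTWYV")
    a = "".join(rng.choice(aas, size=224))
    b = list(a)
    for p in rng.choice(224, size=27, replace=False):
        b[p] = aas[(aas.index(b[p]) + 3) % 20]
    dm = pairwise_distances({"a": a, "b": "".join(b), "c": a})
    assert dm.distances[0, 1] == pytest.approx(27 / 224)
    assert dm.distances[0, 2] == 0.0


def test_fewer_than_three_sequences_rejected():
    with pytest.raises(PhyloError):
        pairwise_distances({"a": "MK", "b": "MK"})


def test_asymmetric_matrix_rejected():
    with pytest.raises(PhyloError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_three_taxon_closed_form():
    dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float))
    tree = neighbor_joining(dm)
    lengths = {c.name: c.branch_length for c in tree.root.children}
    assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0), "c": pytest.approx(3.0)}


def _random_tree_matrix(rng, n):
    """Random additive matrix built from a random binary tree topology."""
    from cmsscan.phylo import TreeNode, PhyloTree

    nodes = [TreeNode(name=f"t{i}", branch_length=float(rng.integers(1, 20)) / 10 + 0.05) for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(branch_length=float(rng.integers(1, 20)) / 10 + 0.05)
        parent.children = [nodes[i], nodes[j]]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    tree = PhyloTree(root=root)
    pairs = tree_path_distances(tree)
    taxa = sorted(tree.root.leaves())
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = pairs[frozenset((taxa[a], taxa[b]))]
    return tree, DistanceMatrix(taxa, d)


@pytest.mark.parametrize("n", [4, 5, 6, 8])
def test_nj_recovers_additive_trees(n, rng):
    for _ in range(5):
        true_tree, dm = _random_tree_matrix(rng, n)
        est = neighbor_joining(dm)
        assert est.splits() == true_tree.splits()
        # branch lengths are recovered too: leaf-pair path distances match
        est_paths = tree_path_distances(est)
        true_paths = tree_path_distances(true_tree)
        for pair, dist in true_paths.items():
            assert est_paths[pair] == pytest.approx(dist, abs=1e-9)


def test_taxon_permutation_gives_isomorphic_tree(rng):
    _, dm = _random_tree_matrix(rng, 6)
    perm = rng.permutation(6)
    dm_perm = DistanceMatrix(
        [dm.taxa[i] for i in perm], dm.distances[np.ix_(perm, perm)]
    )
    assert neighbor_joining(dm).splits() == neighbor_joining(dm_perm).splits()


def test_newick_round_trip(rng):
    _, dm = _random_tree_matrix(rng, 6)
    tree = neighbor_joining(dm)
    text = tree.to_newick()
    back = parse_newick(text)
    assert back.to_newick() == text
    assert sorted(back.root.leaves()) == sorted(tree.root.leaves())


def test_newick_is_biopython_parseable(rng, tmp_path):
    from Bio import Phylo

    _, dm = _random_tree_matrix(rng, 5)
    tree = neighbor_joining(dm)
    path = tmp_path / "t.nwk"
    path.write_text(tree.to_newick() + "\n")
    parsed = Phylo.read(str(path), "newick")
    assert sorted(t.name for t in parsed.get_terminals()) == sorted(dm.taxa)


def test_negative_branch_lengths_clamped():
    d = np.array(
        [[0, 0.1, 0.4, 0.45], [0.1, 0, 0.45, 0.4], [0.4, 0.45, 0, 0.1], [0.45, 0.4, 0.1, 0]]
    )
    tree = neighbor_joining(DistanceMatrix(["a", "b", "c", "d"], d))
    def all_lengths(node):
        out = [] if node.branch_length is None else [node.branch_length]
        for c in node.children:
            out += all_lengths(c)
        return out
    assert all(bl >= 0 for bl in all_lengths(tree.root))
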
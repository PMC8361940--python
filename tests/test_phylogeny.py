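import numpy as np
import pytest

from ssfe.alignment import DistanceMatrix, MultipleAlignment
from ssfe.io_formats import write_newick
from ssfe.phylogeny import (
    bootstrap_support,
    cut_clades,
    midpoint_root,
    nj_tree,
)
from ssfe.treemodel import PhyloTree, TreeNode


def leaf_path_lengths(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths via the depths of lowest common ancestors."""
    depths = tree.depths()
    parents: dict[int, TreeNode | None] = {}
    for node in tree.root.postorder():
        for child in node.children:
            parents[id(child)] = node
    parents[id(tree.root)] = None

    def ancestors(node: TreeNode) -> list[TreeNode]:
        out = [node]
        while parents[id(out[-1])] is not None:
            out.append(parents[id(out[-1])])
        return out

    leaves = tree.leaves()
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(leaves):
        anc_a = {id(x): x for x in ancestors(a)}
        for b in leaves[i + 1 :]:
            lca = next(x for x in ancestors(b) if id(x) in anc_a)
            d = depths[id(a)] + depths[id(b)] - 2 * depths[id(lca)]
            key = tuple(sorted((a.label, b.label)))
            out[key] = d
    return out


def random_binary_tree(rng, n_leaves: int) -> PhyloTree:
    nodes = [TreeNode(label=f"L{i}", length=float(rng.uniform(0.1, 2.0))) for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 2.0)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for x in nodes:
        root.add_child(x)
    return PhyloTree(root, rooted=True)


def tree_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    paths = leaf_path_lengths(tree)
    labels = sorted(tree.leaf_labels())
    n = len(labels)
    d = np.zeros((n, n))
    for (a, b), v in paths.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d)


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        t = nj_tree(d)
        lengths = {leaf.label: leaf.length for leaf in t.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 4.0}

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        d = DistanceMatrix(
            list("ABCD"),
            np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
        )
        t = nj_tree(d)
        assert t.splits() == {frozenset({"C", "D"})}
        paths = leaf_path_lengths(t)
        for (a, b), v in paths.items():
            assert v == pytest.approx(d.get(a, b), abs=1e-9)

    def test_all_equal_matrix_joins_lexicographically_first_pair(self):
        de = np.full((4, 4), 2.0)
        np.fill_diagonal(de, 0.0)
        t = nj_tree(DistanceMatrix(list("ABCD"), de))
        assert write_newick(t) == (
            "((A:1.000000,B:1.000000):0.000000,C:1.000000,D:1.000000);"
        )
        for v in leaf_path_lengths(t).values():
            assert v == pytest.approx(2.0)

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    def test_additivity_recovery_property(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            true = random_binary_tree(rng, int(rng.integers(5, 9)))
            dm = tree_distance_matrix(true)
            est = nj_tree(dm)
            assert est.splits() == true.splits()
            for (a, b), v in leaf_path_lengths(est).items():
                assert v == pytest.approx(dm.get(a, b), abs=1e-9)

    def test_matches_scikit_bio_on_additive_matrix(self):
        import skbio

        rng = np.random.default_rng(7)
        true = random_binary_tree(rng, 6)
        dm = tree_distance_matrix(true)
        ours = nj_tree(dm)
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=dm.labels))
        sk_splits = set()
        leafset = frozenset(dm.labels)
        anchor = min(leafset)
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = leafset - side
            if 1 < len(side) < len(leafset) - 1:
                sk_splits.add(side)
        assert ours.splits() == sk_splits


class TestMidpointRoot:
    def test_chain_midpoint(self):
        x = TreeNode()
        x.add_child(TreeNode(label="A", length=1.0))
        x.add_child(TreeNode(label="B", length=3.0))
        rooted = midpoint_root(PhyloTree(x))
        depths = rooted.depths()
        by_label = {leaf.label: depths[id(leaf)] for leaf in rooted.leaves()}
        assert by_label == {"A": 2.0, "B": 2.0}

    def test_all_zero_lengths_root_adjacent_to_smallest_leaf(self):
        x = TreeNode()
        for lab in ("C", "A", "B"):
            x.add_child(TreeNode(label=lab, length=0.0))
        rooted = midpoint_root(PhyloTree(x))
        # one root child is the leaf A itself (zero-length edge split at 0)
        child_labels = {c.label for c in rooted.root.children}
        assert "A" in child_labels

    def test_rerooting_is_idempotent_on_depths(self):
        x = TreeNode()
        u = x.add_child(TreeNode(length=1.0))
        u.add_child(TreeNode(label="A", length=1.0))
        u.add_child(TreeNode(label="B", length=2.0))
        v = x.add_child(TreeNode(length=1.0))
        v.add_child(TreeNode(label="C", length=1.0))
        v.add_child(TreeNode(label="D", length=2.0))
        once = midpoint_root(PhyloTree(x))
        twice = midpoint_root(once)
        d1 = {leaf.label: once.depths()[id(leaf)] for leaf in once.leaves()}
        d2 = {leaf.label: twice.depths()[id(leaf)] for leaf in twice.leaves()}
        assert d1 == pytest.approx(d2)
        assert once.splits() == twice.splits()


class TestBootstrap:
    def _msa(self):
        # every column supports the AB|CD split
        return MultipleAlignment(
            [("A", "AAAAAAAA"), ("B", "AAAAAAAA"), ("C", "CCCCCCCC"), ("D", "CCCCCCCC")]
        )

    def test_unanimous_signal_gets_full_support(self):
        tree = bootstrap_support(self._msa(), n_reps=100, seed=0, model="p")
        supports = [
            n.support for n in tree.root.postorder() if n.support is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_are_binary(self):
        msa = MultipleAlignment(
            [("A", "AACCAACC"), ("B", "AACCAGCC"), ("C", "CCAACCAA"), ("D", "CCAGCCAA")]
        )
        tree = bootstrap_support(msa, n_reps=1, seed=3, model="p")
        for n in tree.root.postorder():
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_same_seed_reproduces_supports(self):
        msa = MultipleAlignment(
            [("A", "AACCAACC"), ("B", "AACCAGCC"), ("C", "CCAACCAA"), ("D", "CCAGCCAA")]
        )
        t1 = bootstrap_support(msa, n_reps=20, seed=5, model="p")
        t2 = bootstrap_support(msa, n_reps=20, seed=5, model="p")
        assert write_newick(t1) == write_newick(t2)

    def test_supports_lie_in_percentage_range(self):
        msa = MultipleAlignment(
            [
                ("A", "AACCAACCGG"),
                ("B", "AACCAGCCGT"),
                ("C", "CCAACCAATT"),
                ("D", "CCAGCCAATA"),
                ("E", "CAAGCCTATA"),
            ]
        )
        tree = bootstrap_support(msa, n_reps=50, seed=9, model="p")
        for n in tree.root.postorder():
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0


class TestCutClades:
    def _two_cluster_tree(self):
        root = TreeNode()
        for side, labels in (("L", "ABCDE"), ("R", "FGHIJ")):
            mid = root.add_child(TreeNode(length=0.5))
            for lab in labels:
                mid.add_child(TreeNode(label=lab, length=0.1))
        return PhyloTree(root, rooted=True)

    def test_well_separated_clusters_found_at_half_height(self):
        part = cut_clades(self._two_cluster_tree(), 0.5)
        assert len(part) == 2
        assert {c.members for c in part.clades} == {tuple("ABCDE"), tuple("FGHIJ")}

    def test_cut_at_full_height_gives_singletons(self):
        part = cut_clades(self._two_cluster_tree(), 1.0)
        assert len(part) == 10
        assert all(len(c.members) == 1 for c in part.clades)

    def test_cut_near_zero_gives_root_children(self):
        part = cut_clades(self._two_cluster_tree(), 1e-9)
        assert len(part) == 2

    def test_partition_is_a_disjoint_cover(self):
        tree = self._two_cluster_tree()
        for frac in (0.2, 0.5, 0.8, 1.0):
            part = cut_clades(tree, frac)
            members = [m for c in part.clades for m in c.members]
            assert sorted(members) == sorted(tree.leaf_labels())

    def test_requires_rooted_tree(self):
        t = self._two_cluster_tree()
        t.rooted = False
        with pytest.raises(ValueError):
            cut_clades(t, 0.5)
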
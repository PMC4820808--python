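import itertools

import numpy as np
import pytest

from locrep import experiments
from locrep._seq import random_sequence
from locrep.phylo import (Alignment, AlignParams, DistanceMatrix, TreeNode,
                          PhyloTree, bootstrap_support, distance_matrix,
                          jukes_cantor, nj_tree, pairwise_align_score,
                          pairwise_identity, parse_newick, progressive_align)


# ---------------------------------------------------------------------------
# Oracles


def brute_force_pairwise_score(s1, s2, params=None):
    """Exhaustive affine-gap alignment score by DP over explicit states,
    written independently of the production implementation."""
    params = params or AlignParams()
    import functools

    @functools.lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 = none/diag, 1 = in gap consuming s1, 2 = in gap consuming s2
        if i == 0 and j == 0:
            return 0.0 if state == 0 else -1e18
        cands = []
        if i > 0 and j > 0:
            m = params.match if s1[i - 1] == s2[j - 1] else params.mismatch
            if state == 0:
                cands.append(max(best(i - 1, j - 1, st) for st in (0, 1, 2)) + m)
        if i > 0 and state == 1:
            open_ = max(best(i - 1, j, 0), best(i - 1, j, 2)) + params.gap_open
            ext = best(i - 1, j, 1) + params.gap_extend
            cands.append(max(open_, ext))
        if j > 0 and state == 2:
            open_ = max(best(i, j - 1, 0), best(i, j - 1, 1)) + params.gap_open
            ext = best(i, j - 1, 2) + params.gap_extend
            cands.append(max(open_, ext))
        return max(cands) if cands else -1e18

    n1, n2 = len(s1), len(s2)
    return max(best(n1, n2, st) for st in (0, 1, 2))


def enumerate_topologies(labels):
    """All unrooted binary topologies on the labels (3 for 4 taxa, 15 for 5,
    105 for 6), built by sequential edge insertion."""
    base = TreeNode("", [(TreeNode(labels[0]), 1.0), (TreeNode(labels[1]), 1.0),
                         (TreeNode(labels[2]), 1.0)])
    trees = [base]
    for label in labels[3:]:
        new_trees = []
        for t in trees:
            n_edges = _count_edges(t)
            for e in range(n_edges):
                import copy
                t2 = copy.deepcopy(t)
                _insert_at_edge(t2, e, label)
                new_trees.append(t2)
        trees = new_trees
    return trees


def _count_edges(root):
    n = 0
    stack = [root]
    while stack:
        node = stack.pop()
        for child, _ in node.children:
            n += 1
            stack.append(child)
    return n


def _insert_at_edge(root, target, label):
    idx = [0]

    def walk(node):
        for k, (child, bl) in enumerate(node.children):
            if idx[0] == target:
                node.children[k] = (TreeNode("", [(child, bl / 2),
                                                  (TreeNode(label), 1.0)]), bl / 2)
                idx[0] += 1
                return True
            idx[0] += 1
            if walk(child):
                return True
        return False

    walk(root)


def ls_residual(topology, dm: DistanceMatrix) -> float:
    """Least-squares branch-length fit of a topology to a distance matrix:
    residual sum of squares (0 for the generating topology of an additive
    matrix)."""
    labels = dm.labels
    edges = []

    def collect(node, path):
        for child, _ in node.children:
            eid = len(edges)
            edges.append(eid)
            collect(child, path + [eid])
            if not child.children:
                leaf_paths[child.label] = path + [eid]

    leaf_paths = {}
    edges.clear()
    collect(topology, [])
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        pi = set(leaf_paths[labels[i]])
        pj = set(leaf_paths[labels[j]])
        for e in pi.symmetric_difference(pj):
            A[r, e] = 1.0
        y[r] = dm.d[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


# ---------------------------------------------------------------------------
# Aligner


class TestProgressiveAlign:
    def test_identical_sequences_gapless(self):
        aln = progressive_align({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert aln.rows[0] == aln.rows[1] == "ACGTACGT"
        assert pairwise_identity(aln)[0, 1] == 1.0

    def test_pairwise_score_matches_exhaustive_oracle(self):
        cases = [("ACGT", "ACT"), ("AAAA", "AAA"), ("ACGTGTCA", "ACGCA"),
                 ("GATTACA", "GCATGCT")]
        for s1, s2 in cases:
            assert pairwise_align_score(s1, s2) == pytest.approx(
                brute_force_pairwise_score(s1, s2)), (s1, s2)

    def test_single_gap_for_single_deletion(self):
        aln = progressive_align({"a": "ACGT", "b": "ACT"})
        gaps = sum(r.count("-") for r in aln.rows)
        assert gaps == 1

    def test_majority_column_recovers_root(self):
        """Five low-divergence descendants of one root: the majority base per
        aligned column equals the root base at >= 95% of columns."""
        rng = np.random.default_rng(4)
        root = random_sequence(600, 0.5, rng)
        tree = "((a:0.02,b:0.02):0.01,(c:0.02,d:0.02):0.01,e:0.03);"
        from locrep.synthetic import simulate_ortholog_set
        leaves = simulate_ortholog_set(tree, root, 7)
        aln = progressive_align(leaves)
        mat = aln.matrix()
        agree = 0
        for col, root_base in zip(mat.T, root.encode()):
            vals, counts = np.unique(col, return_counts=True)
            if vals[np.argmax(counts)] == root_base:
                agree += 1
        assert agree / len(root) >= 0.95

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({"a": "", "b": "ACGT"})


class TestIdentityAndDistance:
    def test_gap_columns_excluded(self):
        aln = Alignment(["x", "y"], ["AC-T", "ACGT"])
        assert pairwise_identity(aln)[0, 1] == 1.0

    def test_no_comparable_columns_is_nan(self):
        aln = Alignment(["x", "y"], ["A---", "-CGT"])
        assert np.isnan(pairwise_identity(aln)[0, 1])

    def test_row_reordering_invariance(self, rng):
        rows = ["".join(rng.choice(list("ACGT-"), 60)) for _ in range(4)]
        labels = ["a", "b", "c", "d"]
        ident = pairwise_identity(Alignment(labels, rows))
        perm = [2, 0, 3, 1]
        ident2 = pairwise_identity(Alignment([labels[i] for i in perm],
                                             [rows[i] for i in perm]))
        for i, pi in enumerate(perm):
            for j, pj in enumerate(perm):
                assert ident2[i, j] == pytest.approx(ident[pi, pj], nan_ok=True)

    def test_jc_distance_dominates_p_distance(self):
        for p in np.linspace(0.01, 0.74, 40):
            jc = -0.75 * np.log(1 - 4 * p / 3)
            assert jc >= p

    def test_jc_saturation_ceiling(self):
        aln = Alignment(["x", "y"], ["A" * 100, "C" * 100])
        d = jukes_cantor(aln)
        assert d.d[0, 1] == 10.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(dm)
        bl = {child.label: l for child, l in tree.root.children}
        assert bl == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_additive_recovery(self):
        """NJ is consistent on additive matrices: exact topology and branch
        lengths for ((A:1,B:2):1,(C:3,D:1))."""
        gen = parse_newick("((A:1,B:2):1,(C:3,D:1):0);")
        dm = experiments.tree_distance_matrix(gen)
        tree = nj_tree(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # leaf branch lengths recovered exactly
        lengths = {}

        def walk(node):
            for child, bl in node.children:
                if not child.children:
                    lengths[child.label] = bl
                walk(child)

        walk(tree.root)
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0})

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], d))

    def test_nj_agrees_with_exhaustive_least_squares(self):
        """On random additive matrices (4-6 taxa) the NJ topology ties the
        best least-squares topology from exhaustive enumeration."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            labels = [f"t{i}" for i in range(n)]
            gen = experiments.random_binary_tree(labels, rng)
            dm = experiments.tree_distance_matrix(gen)
            nj = nj_tree(dm)
            residuals = []
            for topo in enumerate_topologies(labels):
                pt = PhyloTree(topo, sorted(labels))
                residuals.append((ls_residual(topo, dm), pt.bipartitions()))
            best_rss, best_bps = min(residuals, key=lambda t: t[0])
            assert best_rss == pytest.approx(0.0, abs=1e-12)
            assert nj.bipartitions() == best_bps


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(5)]
        aln = Alignment(list("abcde"), rows)
        _, s1 = bootstrap_support(aln, n_boot=30, seed=5)
        _, s2 = bootstrap_support(aln, n_boot=30, seed=5)
        assert s1 == s2

    def test_two_clade_signal_highly_supported(self):
        support, _ = experiments.two_clade_replicate(21)
        assert support >= 95

    def test_no_signal_alignment_low_support(self):
        """I.i.d. random columns carry no phylogenetic signal: internal
        branches rarely exceed 70% support."""
        weak = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rows = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(6)]
            aln = Alignment(list("abcdef"), rows)
            _, supports = bootstrap_support(aln, n_boot=50, seed=seed)
            if max(supports.values(), default=0) <= 70:
                weak += 1
        assert weak >= 9

    def test_too_few_taxa_or_replicates(self):
        aln = Alignment(["a", "b", "c"], ["ACGT", "ACGT", "ACGT"])
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_boot=10, seed=0)


class TestNewick:
    def test_roundtrip_with_supports(self):
        txt = "((A:1,B:2)95:0.5,(C:3,D:1)80:0.5);"
        root = parse_newick(txt)
        tree = PhyloTree(root, ["A", "B", "C", "D"])
        again = parse_newick(tree.newick())
        assert sorted(again.leaves()) == ["A", "B", "C", "D"]
        supports = []

        def walk(node):
            if node.support is not None:
                supports.append(node.support)
            for c, _ in node.children:
                walk(c)

        walk(again)
        assert sorted(supports) == [80, 95]

    def test_branch_lengths_parsed(self):
        root = parse_newick("(a:0.1,b:0.25);")
        assert [bl for _, bl in root.children] == [0.1, 0.25]
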
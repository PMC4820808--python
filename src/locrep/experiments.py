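"""Replicated study-condition experiments: power/calibration of the burden
comparison, ChIP enrichment calibration, NJ topology recovery, and two-clade
bootstrap support. These drive both the test suite and the reproduction
script; every experiment is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic
from .burden import compare_burdens
from .chip import EnrichmentResult, from_multimapped_reads, permutation_poisson_test
from .formats_io import GenomicInterval
from .phylo import (Alignment, DistanceMatrix, TreeNode, PhyloTree,
                    bootstrap_support, nj_tree)

# Burden regime: the LR-rich class carries ~25 LRs per 100 kb, the LR-poor
# class ~6 (a fourfold difference); tandem rates are equal in both classes.
LR_RATE_RICH = 25.0
LR_RATE_POOR = 6.0
TR_RATE = 10.0


def burden_replicate(seed: int, rate_a: float, rate_b: float,
                     n_genes: int = 200) -> tuple[float, float]:
    """One replicate: (LR p-value, TR p-value) comparing two gene classes."""
    rng = np.random.default_rng(seed)
    a = synthetic.simulate_burden_counts(n_genes, rate_a, TR_RATE, rng)
    b = synthetic.simulate_burden_counts(n_genes, rate_b, TR_RATE, rng)
    p_lr = compare_burdens(a.lr_per_kb, b.lr_per_kb).p_value
    p_tr = compare_burdens(a.tr_per_kb, b.tr_per_kb).p_value
    return p_lr, p_tr


def burden_power_experiment(n_rep: int = 50, seed: int = 0) -> pd.DataFrame:
    """LR-rich vs LR-poor classes, equal TR rates, n_rep replicates."""
    rows = [burden_replicate(seed + 1000 * i, LR_RATE_RICH, LR_RATE_POOR)
            for i in range(n_rep)]
    return pd.DataFrame(rows, columns=["p_lr", "p_tr"])


def burden_null_experiment(n_rep: int = 200, seed: int = 0,
                           rate: float = 15.0) -> np.ndarray:
    """Equal LR rates in both classes; returns the LR p-values."""
    return np.array([burden_replicate(seed + 1000 * i, rate, rate)[0]
                     for i in range(n_rep)])


# ---------------------------------------------------------------------------
# ChIP calibration


def chip_replicate(seed: int, fold: float, genome_length: int = 20_000,
                   copies: int = 6, family_length: int = 100,
                   depth: int = 100, read_length: int = 50,
                   n_perm: int = 100) -> EnrichmentResult:
    """One ChIP experiment: plant a near-identical repeat family, draw ChIP
    reads at the given fold over it and input reads uniformly (both at the
    stated genome-wide depth), multi-map within 1 mismatch, and run the
    permutation-Poisson enrichment test."""
    n_reads = depth * genome_length // read_length
    cfg = synthetic.SimulationConfig(
        seed=seed, genome_length=genome_length, gc_content=0.45,
        planted_families=[synthetic.PlantSpec(
            "BOUND", family_length, copies, divergence=0.02, host_locus="lnc000")],
        gene_model=synthetic.GeneClassModel(n_lnc=1, n_mrna=0, lnc_length=4000),
        chip_model=synthetic.ChipModel("BOUND", fold, read_length, n_reads, n_reads),
    )
    assembly, _genes, _te, truth = synthetic.simulate_genome(cfg)
    bound = [GenomicInterval(r.chrom, r.start, r.end)
             for r in truth.family_instances("BOUND").itertuples()]
    chip_reads, input_reads = synthetic.simulate_chip_reads(
        assembly, bound, cfg.chip_model, seed + 1)
    chip_set = from_multimapped_reads(chip_reads, assembly.lengths)
    input_set = from_multimapped_reads(input_reads, assembly.lengths)
    return permutation_poisson_test("BOUND", bound, assembly, chip_set, input_set,
                                    n_perm=n_perm, seed=seed + 2)


def chip_calibration_experiment(fold: float, n_rep: int, seed: int = 0,
                                **kwargs) -> np.ndarray:
    return np.array([chip_replicate(seed + 10_000 * i, fold, **kwargs).p_value
                     for i in range(n_rep)])


# ---------------------------------------------------------------------------
# Phylogeny experiments


def random_binary_tree(labels: list[str], rng: np.random.Generator,
                       blen_range: tuple[float, float] = (0.05, 1.0)) -> TreeNode:
    """Random unrooted binary topology by sequential leaf insertion on a
    uniformly chosen edge, with uniform branch lengths."""

    def bl() -> float:
        return float(rng.uniform(*blen_range))

    root = TreeNode("", [(TreeNode(labels[0]), bl()), (TreeNode(labels[1]), bl()),
                         (TreeNode(labels[2]), bl())])
    for label in labels[3:]:
        edges = []

        def collect(node):
            for idx, (child, _) in enumerate(node.children):
                edges.append((node, idx))
                collect(child)

        collect(root)
        node, idx = edges[rng.integers(len(edges))]
        child, old_bl = node.children[idx]
        split = TreeNode("", [(child, old_bl / 2), (TreeNode(label), bl())])
        node.children[idx] = (split, old_bl / 2)
    return root


def tree_distance_matrix(root: TreeNode) -> DistanceMatrix:
    """Additive (path-length) distances between the leaves of a tree."""
    leaves: list[tuple[str, list[tuple[TreeNode, float]]]] = []

    def collect(node, path):
        if not node.children:
            leaves.append((node.label, list(path)))
        for child, blen in node.children:
            collect(child, path + [(child, blen)])

    collect(root, [])
    labels = sorted(l for l, _ in leaves)
    by_label = dict(leaves)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = by_label[labels[i]], by_label[labels[j]]
            shared = 0
            for (a, _), (b, _) in zip(pi, pj):
                if a is b:
                    shared += 1
                else:
                    break
            dist = sum(bl for _, bl in pi[shared:]) + sum(bl for _, bl in pj[shared:])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d, "p_distance")


def tree_bipartitions(root: TreeNode) -> set[frozenset]:
    labels = sorted(root.leaves())
    return PhyloTree(root, labels).bipartitions()


def nj_recovery_experiment(n_trees: int = 200, seed: int = 0,
                           n_taxa_range: tuple[int, int] = (4, 6)) -> float:
    """Fraction of random additive matrices whose generating topology NJ
    recovers exactly (bipartition sets equal)."""
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_trees):
        n_taxa = int(rng.integers(n_taxa_range[0], n_taxa_range[1] + 1))
        labels = [f"t{i}" for i in range(n_taxa)]
        tree = random_binary_tree(labels, rng)
        dm = tree_distance_matrix(tree)
        recovered = nj_tree(dm)
        if recovered.bipartitions() == tree_bipartitions(tree):
            n_ok += 1
    return n_ok / n_trees


# Two-clade regime mirroring the within-order (~90%) vs cross-order (~60%)
# identity contrast: leaf branches ~0.054 subs/site, stem branches ~0.232.
TWO_CLADE_TREE = ("((A1:0.0537,(A2:0.0437,A3:0.0437):0.01):0.2321,"
                  "(B1:0.0537,(B2:0.0437,B3:0.0437):0.01):0.2321);")
CLADE_SPLIT = frozenset({"B1", "B2", "B3"})


def two_clade_replicate(seed: int, seq_length: int = 5000, n_boot: int = 100
                        ) -> tuple[int, Alignment]:
    """Simulate orthologs down the two-clade tree, bootstrap the NJ tree, and
    return the support of the clade bipartition. The simulated sequences are
    indel-free and equal length, so they are used as alignment columns
    directly."""
    from ._seq import random_sequence
    rng = np.random.default_rng(seed)
    root_seq = random_sequence(seq_length, 0.45, rng)
    leaves = synthetic.simulate_ortholog_set(TWO_CLADE_TREE, root_seq, seed + 1)
    aln = Alignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])
    _tree, supports = bootstrap_support(aln, n_boot=n_boot, seed=seed + 2)
    return supports.get(CLADE_SPLIT, 0), aln


def two_clade_experiment(n_rep: int = 20, seed: int = 0, **kwargs) -> np.ndarray:
    return np.array([two_clade_replicate(seed + 500 * i, **kwargs)[0]
                     for i in range(n_rep)])
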
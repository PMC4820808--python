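import numpy as np
import pytest

from locrep._seq import random_sequence, revcomp
from locrep.formats_io import GenomeAssembly, GeneAnnotation, GenomicInterval
from locrep.locality import (ConsensusMapper, LocalityParams, MappingParams,
                             classify_locality, compute_burden, map_consensus)
from locrep.synthetic import mutate_copy
from locrep.tandem import TandemArray


def _genome_with_copies(rng, cons, copies):
    """copies: list of (sequence, strand). Returns assembly and spans."""
    parts, spans = [], []
    pos = 0
    for seq, strand in copies:
        flank = random_sequence(500, 0.5, rng)
        parts.append(flank)
        pos += len(flank)
        placed = seq if strand == "+" else revcomp(seq)
        parts.append(placed)
        spans.append((pos, pos + len(placed)))
        pos += len(placed)
    parts.append(random_sequence(500, 0.5, rng))
    return GenomeAssembly({"chr1": "".join(parts)}), spans


class TestMapConsensus:
    def test_exact_copy_found_at_identity_one(self, rng):
        cons = random_sequence(300, 0.5, rng)
        asm, spans = _genome_with_copies(rng, cons, [(cons, "+")])
        (hit,) = map_consensus(asm, cons)
        iv, ident = hit
        assert ident == 1.0
        assert (iv.start, iv.end) == spans[0]

    def test_reverse_strand_copy(self, rng):
        cons = random_sequence(300, 0.5, rng)
        asm, spans = _genome_with_copies(rng, cons, [(cons, "-")])
        (hit,) = map_consensus(asm, cons)
        assert hit[0].strand == "-"
        assert (hit[0].start, hit[0].end) == spans[0]

    def test_diverged_copy_identity_tracks_divergence(self):
        """A copy at 20% divergence maps at identity 0.80 +/- 0.03."""
        idents = []
        for s in range(10):
            rng = np.random.default_rng(s)
            cons = random_sequence(400, 0.5, rng)
            copy = mutate_copy(cons, 0.20, 0.0, rng)
            asm, _ = _genome_with_copies(rng, cons, [(copy, "+"), (cons, "+")])
            hits = map_consensus(asm, cons)
            idents.append(min(i for _, i in hits))
        assert abs(np.mean(idents) - 0.80) < 0.03

    def test_short_truncation_below_length_fraction_not_reported(self, rng):
        cons = random_sequence(400, 0.5, rng)
        trunc = cons[:160]  # 40% of the consensus
        asm, _ = _genome_with_copies(rng, cons, [(trunc, "+")])
        assert map_consensus(asm, cons) == []

    def test_consensus_too_short_errors(self, rng):
        asm, _ = _genome_with_copies(rng, "ACGT" * 30, [("ACGT" * 30, "+")])
        with pytest.raises(ValueError):
            map_consensus(asm, "ACGTACGTACGTACGTACG", MappingParams(k_map=12))


def _gene(gid, start, end, biotype="lncRNA"):
    return GeneAnnotation(gid, GenomicInterval("chr1", start, end, "+"), biotype)


def _hits(spans):
    return [(GenomicInterval("chr1", s, e), 0.95) for s, e in spans]


class TestClassifyLocality:
    def test_all_inside_is_local(self):
        genes = [_gene("g1", 0, 50_000)]
        call = classify_locality("f", _hits([(i * 1000, i * 1000 + 100)
                                             for i in range(1, 13)]), genes)
        assert call.call == "LOCAL"
        assert call.host_locus == "g1"
        assert call.locality_fraction == 1.0

    def test_outside_instances_flagged(self):
        """8/10 inside -> LOCAL; the two outside copies, shorter than the
        in-locus median and 400 kb apart, carry both dispersal flags."""
        genes = [_gene("g1", 0, 50_000)]
        inside = [(i * 1000, i * 1000 + 100) for i in range(1, 9)]
        outside = [(100_000, 100_060), (500_000, 500_060)]
        call = classify_locality("f", _hits(inside + outside), genes)
        assert call.call == "LOCAL" and call.locality_fraction == 0.8
        assert len(call.outside_flags) == 2
        for fl in call.outside_flags:
            assert fl.shorter_than_locus_median
            assert fl.nearest_outside_neighbor_distance == 400_000

    def test_spread_over_genes_is_dispersed(self):
        genes = [_gene(f"g{i}", i * 100_000, i * 100_000 + 50_000) for i in range(5)]
        spans = [(i * 100_000 + 10_000 + j, i * 100_000 + 10_100 + j)
                 for i in range(5) for j in (0, 200)]
        call = classify_locality("f", _hits(spans), genes)
        assert call.call == "DISPERSED"
        assert call.host_locus is None
        assert call.locality_fraction == pytest.approx(0.2)

    def test_no_loci_warns_and_disperses(self, caplog):
        with caplog.at_level("WARNING"):
            call = classify_locality("f", _hits([(0, 100), (1000, 1100)]), [])
        assert call.call == "DISPERSED"
        assert any("no loci" in r.message for r in caplog.records)

    def test_too_few_instances_errors(self):
        with pytest.raises(ValueError):
            classify_locality("f", _hits([(0, 100)]), [_gene("g", 0, 1000)])


class TestComputeBurden:
    def test_per_kb_normalization(self):
        """25 in-locus instances in a 100 kb gene: 0.25 LRs per kb."""
        from locrep.locality import LocalityCall
        gene = _gene("g1", 0, 100_000)
        call = LocalityCall("f", "LOCAL", "g1", 1.0, 25)
        inst = {"f": _hits([(i * 3000, i * 3000 + 150) for i in range(1, 26)])}
        df = compute_burden([call], inst, [], [gene])
        assert df.loc[0, "n_lr"] == 25
        assert df.loc[0, "lr_per_kb"] == pytest.approx(0.25)

    def test_gene_without_repeats(self):
        df = compute_burden([], {}, [], [_gene("g1", 0, 10_000)])
        assert (df.loc[0, ["n_lr", "n_tr", "lr_per_kb", "tr_per_kb"]] == 0).all()

    def test_tr_overlap_counted(self):
        arrays = [TandemArray(GenomicInterval("chr1", 500, 700), 10, 20, "A" * 10, 1.0)]
        df = compute_burden([], {}, arrays, [_gene("g1", 0, 10_000)])
        assert df.loc[0, "n_tr"] == 1

    def test_zero_length_gene_rejected(self):
        gene = _gene("g1", 0, 1)
        gene.interval = GenomicInterval("chr1", 0, 1)
        # zero-length spans cannot even be constructed; the guard is the
        # GenomicInterval invariant
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)

    def test_burden_additivity_over_disjoint_gene_sets(self):
        from locrep.locality import LocalityCall
        genes_a = [_gene("a1", 0, 20_000)]
        genes_b = [_gene("b1", 50_000, 90_000)]
        call = LocalityCall("f", "LOCAL", "a1", 1.0, 4)
        inst = {"f": _hits([(1000, 1100), (2000, 2100), (3000, 3100), (4000, 4100)])}
        both = compute_burden([call], inst, [], genes_a + genes_b)
        parts = (compute_burden([call], inst, [], genes_a),
                 compute_burden([call], inst, [], genes_b))
        import pandas as pd
        assert both.equals(pd.concat(parts, ignore_index=True))

    def test_truth_counts_on_demo_genome(self, demo_sim, demo_discovery):
        """Per-gene LR counts match the truth table for fully recovered
        families."""
        from locrep.locality import classify_locality as cl
        truth, genes = demo_sim["truth"], demo_sim["genes"]
        mapper = ConsensusMapper(demo_sim["assembly"])
        calls, imap = [], {}
        for fam in demo_discovery["families"]:
            hits = mapper.map(fam.consensus)
            if len(hits) >= 2:
                imap[fam.family_id] = hits
                calls.append(cl(fam.family_id, hits, genes))
        df = compute_burden(calls, imap, [], genes).set_index("gene_id")
        truth_genes = truth.genes.set_index("gene_id")
        hosts = truth.instances[truth.instances.inside_host].host.unique()
        for gid in hosts:
            assert df.loc[gid, "n_lr"] == truth_genes.loc[gid, "n_lr"], gid
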
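import numpy as np
import pytest

from locrep._seq import random_sequence, revcomp
from locrep.discovery import (DiscoveryParams, SeedFamily, discover_repeats,
                              extend_seed, find_seeds, mask_te)
from locrep.formats_io import GenomeAssembly, GenomicInterval


def asm(seq: str) -> GenomeAssembly:
    return GenomeAssembly({"chr1": seq})


class TestMaskTe:
    def test_empty_mask_is_identity(self):
        m = mask_te(asm("ACGTAC"), [])
        assert m.assembly.sequences["chr1"] == "ACGTAC"

    def test_direct_substitution(self):
        m = mask_te(asm("ACGTAC"), [GenomicInterval("chr1", 2, 4)])
        assert m.assembly.sequences["chr1"] == "ACNNAC"

    def test_union_semantics_for_overlaps(self):
        m = mask_te(asm("ACGTACGT"), [GenomicInterval("chr1", 0, 4),
                                      GenomicInterval("chr1", 2, 6)])
        assert m.assembly.sequences["chr1"].count("N") == 6

    def test_out_of_bounds_errors(self):
        with pytest.raises(ValueError):
            mask_te(asm("ACGT"), [GenomicInterval("chr1", 2, 10)])

    def test_original_untouched(self):
        a = asm("ACGTAC")
        mask_te(a, [GenomicInterval("chr1", 0, 6)])
        assert a.sequences["chr1"] == "ACGTAC"


class TestFindSeeds:
    def test_homopolymer_sliding_window_count(self):
        m = mask_te(asm("A" * 100), [])
        (fam,) = find_seeds(m, k=16, min_count=2)
        assert fam.count == 100 - 16 + 1

    def test_random_sequence_has_no_high_count_seeds(self):
        """Expected 16-mer collisions in 10 kb are far below 1."""
        for seed in range(5):
            seq = random_sequence(10_000, 0.5, np.random.default_rng(seed))
            assert find_seeds(mask_te(asm(seq), []), 16, 5) == []

    def test_planted_copies_support_every_seed(self, rng):
        copy = random_sequence(200, 0.5, rng)
        parts = []
        for _ in range(5):
            parts.extend([random_sequence(300, 0.5, rng), copy])
        fams = find_seeds(mask_te(asm("".join(parts)), []), 16, 2)
        per_kmer = {f.kmer: f.count for f in fams}
        from locrep._seq import canonical_kmer
        constituent = {canonical_kmer(copy[i:i + 16])[0] for i in range(len(copy) - 15)}
        assert all(per_kmer.get(km, 0) >= 5 for km in constituent)
        assert len(constituent) >= 200 - 16 + 1 - 5  # allow a few self-collisions

    def test_n_containing_kmers_excluded(self):
        m = mask_te(asm("A" * 100), [GenomicInterval("chr1", 50, 51)])
        (fam,) = find_seeds(m, 16, 2)
        # of the 85 16-mer windows, the 16 covering the N are excluded
        assert fam.count == 85 - 16

    def test_preconditions(self):
        m = mask_te(asm("A" * 100), [])
        with pytest.raises(ValueError):
            find_seeds(m, k=4)
        with pytest.raises(ValueError):
            find_seeds(m, min_count=1)


class TestExtendSeed:
    def _planted(self, rng, n_copies=5, length=200, divergence=0.0):
        from locrep.synthetic import mutate_copy
        cons = random_sequence(length, 0.5, rng)
        parts, positions = [], []
        pos = 0
        for _ in range(n_copies):
            flank = random_sequence(300, 0.5, rng)
            parts.append(flank)
            pos += len(flank)
            copy = mutate_copy(cons, divergence, 0.0, rng) if divergence else cons
            parts.append(copy)
            positions.append((pos, pos + len(copy)))
            pos += len(copy)
        parts.append(random_sequence(300, 0.5, rng))
        return cons, positions, mask_te(asm("".join(parts)), [])

    def test_identical_copies_recover_exact_consensus(self, rng):
        cons, positions, masked = self._planted(rng)
        seed_kmer = cons[92:108]
        seeds = [f for f in find_seeds(masked, 16, 2) if f.kmer in (seed_kmer, revcomp(seed_kmer))]
        fam = extend_seed(masked, seeds[0], DiscoveryParams())
        assert fam.consensus in (cons, revcomp(cons))
        assert fam.n_instances == 5
        assert all(ident == 1.0 for _, ident in fam.instances)
        got = sorted((iv.start, iv.end) for iv, _ in fam.instances)
        assert got == positions

    def test_single_copy_below_min_count(self, rng):
        cons, _, masked = self._planted(rng, n_copies=1)
        fam = extend_seed(masked, SeedFamily(cons[:16], [("chr1", 300, "+")]),
                          DiscoveryParams(min_count=2))
        assert fam is None

    def test_diverged_copies_majority_vote(self):
        """Copies at 10% divergence: consensus >= 95% identical to the
        planted sequence, length within 10 bp (majority over >= 5 copies
        corrects per-column noise)."""
        from locrep.evaluate import consensus_identity
        ok_ident, ok_len = [], []
        for s in range(20):
            rng = np.random.default_rng(s)
            cons, _, masked = self._planted(rng, n_copies=8, divergence=0.10)
            seeds = find_seeds(masked, 16, 3)
            fam = extend_seed(masked, seeds[0], DiscoveryParams())
            assert fam is not None
            ok_ident.append(consensus_identity(fam.consensus, cons) >= 0.95)
            ok_len.append(abs(len(fam.consensus) - len(cons)) <= 10)
        assert np.mean(ok_ident) >= 0.9
        assert np.mean(ok_len) >= 0.9


class TestDiscoverRepeats:
    def _three_family_genome(self, seed=0):
        rng = np.random.default_rng(seed)
        parts, truth = [], {}
        pos = 0
        for fid, (length, copies) in enumerate([(150, 5), (250, 4), (400, 3)]):
            cons = random_sequence(length, 0.5, rng)
            truth[fid] = {"cons": cons, "spans": []}
            for _ in range(copies):
                flank = random_sequence(400, 0.5, rng)
                parts.append(flank)
                pos += len(flank)
                parts.append(cons)
                truth[fid]["spans"].append((pos, pos + length))
                pos += length
        parts.append(random_sequence(400, 0.5, rng))
        return mask_te(asm("".join(parts)), []), truth

    def test_disjoint_planted_families_recovered(self):
        masked, truth = self._three_family_genome()
        fams = discover_repeats(masked)
        assert len(fams) == 3
        planted_spans = sorted(s for t in truth.values() for s in t["spans"])
        got = sorted((iv.start, iv.end) for f in fams for iv, _ in f.instances)
        assert len(got) == len(planted_spans)
        for (gs, ge), (ps, pe) in zip(got, planted_spans):
            assert abs(gs - ps) <= 10 and abs(ge - pe) <= 10

    def test_fully_masked_genome(self):
        masked = mask_te(asm("A" * 5000), [GenomicInterval("chr1", 0, 5000)])
        assert discover_repeats(masked) == []

    def test_determinism(self):
        masked, _ = self._three_family_genome(3)
        a = discover_repeats(masked)
        b = discover_repeats(masked)
        assert [(f.family_id, f.consensus, f.instances) for f in a] == \
               [(f.family_id, f.consensus, f.instances) for f in b]

    def test_min_count_monotonicity(self):
        masked, _ = self._three_family_genome(1)
        counts = [len(discover_repeats(masked, DiscoveryParams(min_count=c)))
                  for c in (2, 3, 4, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_strand_closure(self):
        """Discovery on the reverse-complemented genome yields families whose
        consensi are reverse complements (same instance counts)."""
        masked, _ = self._three_family_genome(4)
        rc = mask_te(asm(revcomp(masked.assembly.sequences["chr1"])), [])
        fwd = discover_repeats(masked)
        rev = discover_repeats(rc)
        fwd_cons = {min(f.consensus, revcomp(f.consensus)): f.n_instances for f in fwd}
        rev_cons = {min(f.consensus, revcomp(f.consensus)): f.n_instances for f in rev}
        assert fwd_cons == rev_cons
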
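import numpy as np
import pytest

from locrep import synthetic
from locrep._seq import random_sequence, revcomp, seq_to_u8
from locrep.formats_io import GenomicInterval


class TestMutateCopy:
    def test_zero_divergence_is_identity(self, rng):
        assert synthetic.mutate_copy("ACGTACGT", 0.0, 0.0, rng) == "ACGTACGT"

    def test_divergence_out_of_range(self, rng):
        with pytest.raises(ValueError):
            synthetic.mutate_copy("ACGT", 0.6, 0.0, rng)

    def test_empty_consensus(self, rng):
        with pytest.raises(ValueError):
            synthetic.mutate_copy("", 0.1, 0.0, rng)

    def test_realized_divergence_matches_binomial_expectation(self):
        """Hamming distance / length stays within 0.10 +/- 0.01 of the
        requested rate over 50 seeds (10 kb consensus, no indels)."""
        cons = random_sequence(10_000, 0.5, np.random.default_rng(0))
        a = seq_to_u8(cons)
        rates = []
        for seed in range(50):
            mut = synthetic.mutate_copy(cons, 0.10, 0.0, np.random.default_rng(seed))
            rates.append(float((seq_to_u8(mut) != a).mean()))
        assert abs(np.mean(rates) - 0.10) < 0.01

    def test_indels_change_length(self):
        rng = np.random.default_rng(7)
        mut = synthetic.mutate_copy("A" * 1000, 0.0, 0.05, rng)
        assert mut != "A" * 1000 or len(mut) != 1000


class TestSimulateGenome:
    def test_forced_locality(self):
        cfg = synthetic.SimulationConfig(
            seed=3, genome_length=50_000,
            planted_families=[synthetic.PlantSpec("F", 150, 5, host_locus="lnc000",
                                                  locality_fraction=1.0)],
            gene_model=synthetic.GeneClassModel(n_lnc=1, n_mrna=0, lnc_length=8000))
        _, genes, _, truth = synthetic.simulate_genome(cfg)
        host = genes[0].interval
        inst = truth.family_instances("F")
        assert len(inst) == 5
        assert all(host.start <= r.start and r.end <= host.end for r in inst.itertuples())

    def test_no_planted_overlap(self, demo_sim):
        rows = sorted(
            [(r.start, r.end) for r in demo_sim["truth"].instances.itertuples()]
            + [(r.start, r.end) for r in demo_sim["truth"].tandem_arrays.itertuples()]
            + [(iv.start, iv.end) for iv in demo_sim["te"]])
        for (s1, e1), (s2, e2) in zip(rows, rows[1:]):
            assert e1 <= s2

    def test_truth_identity_consistent_with_genome(self, demo_sim):
        """Re-extracting each planted instance reproduces the recorded
        identity to the consensus within 1%."""
        from locrep.evaluate import consensus_identity
        truth, asm = demo_sim["truth"], demo_sim["assembly"]
        for r in truth.instances.itertuples():
            seq = asm.fetch(r.chrom, r.start, r.end)
            if r.strand == "-":
                seq = revcomp(seq)
            cons = truth.consensi[r.family_id]
            assert abs(consensus_identity(seq, cons) - r.identity) < 0.01

    def test_determinism_byte_identical(self, tmp_path):
        from locrep.formats_io import write_fasta
        for sub in ("a", "b"):
            cfg = synthetic.demo_config(seed=9)
            asm, _, _, _ = synthetic.simulate_genome(cfg)
            write_fasta(tmp_path / f"{sub}.fa", asm)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_infeasible_placement_errors(self):
        cfg = synthetic.SimulationConfig(
            seed=0, genome_length=2000,
            planted_families=[synthetic.PlantSpec("F", 400, 4, host_locus="lnc000")],
            gene_model=synthetic.GeneClassModel(n_lnc=1, n_mrna=0, lnc_length=900))
        with pytest.raises(ValueError):
            synthetic.simulate_genome(cfg)


def test_firre_like_preset_medians():
    """The default study conditions plant 13 local families with median
    consensus length 167 bp and median 12 copies."""
    cfg = synthetic.firre_like_config(0)
    local = [s for s in cfg.planted_families if s.host_locus]
    assert len(local) == 13
    assert np.median([s.consensus_length for s in local]) == 167
    assert np.median([s.copy_number for s in local]) == 12
    assert max(s.divergence for s in local) <= 0.10


def test_burden_counts_hit_target_rates(rng):
    """Realized per-100kb burdens within 20% of the 25 vs 6 targets at 200
    genes per class."""
    for target in (25.0, 6.0):
        df = synthetic.simulate_burden_counts(200, target, 10.0, rng)
        realized = df.n_lr.sum() / (df.length.sum() / 100_000)
        assert abs(realized - target) / target < 0.20


class TestOrthologSimulation:
    def test_zero_branch_lengths_identity(self):
        leaves = synthetic.simulate_ortholog_set("((a:0,b:0):0,c:0);", "ACGT" * 25, 5)
        assert set(leaves.values()) == {"ACGT" * 25}

    def test_negative_branch_length_errors(self):
        with pytest.raises(ValueError):
            synthetic.simulate_ortholog_set("(a:-0.1,b:0.1);", "ACGT" * 10, 5)

    def test_jukes_cantor_pairwise_identity(self):
        """Two leaves at b=0.1 each from the root: expected identity
        1 - 3/4 (1 - e^(-4*0.2/3)) ~ 0.862, observed within 0.03 at 10 kb."""
        root = random_sequence(10_000, 0.5, np.random.default_rng(1))
        leaves = synthetic.simulate_ortholog_set("(a:0.1,b:0.1);", root, 11)
        a, b = seq_to_u8(leaves["a"]), seq_to_u8(leaves["b"])
        expected = 1 - 0.75 * (1 - np.exp(-4 * 0.2 / 3))
        assert abs(float((a == b).mean()) - expected) < 0.03


class TestChipReads:
    def test_multimapping_over_identical_copies(self):
        """A read drawn from a family of identical copies is reported at
        every copy."""
        rng = np.random.default_rng(0)
        copy = random_sequence(100, 0.5, rng)
        parts = [random_sequence(200, 0.5, rng)]
        for _ in range(20):
            parts.extend([copy, random_sequence(200, 0.5, rng)])
        from locrep.formats_io import GenomeAssembly
        asm = GenomeAssembly({"chr1": "".join(parts)})
        regions = []
        pos = 200
        for _ in range(20):
            regions.append(GenomicInterval("chr1", pos, pos + 100))
            pos += 300
        model = synthetic.ChipModel("F", 5.0, 50, 300, 300)
        chip, _ = synthetic.simulate_chip_reads(asm, regions, model, 3)
        multi = [locs for _, locs in chip if len(locs) > 1]
        assert multi, "expected multi-mapped reads from the repeat family"
        # a read fully inside a copy maps to all 20 copies
        assert max(len(locs) for locs in multi) == 20

    def test_sam_roundtrip(self, tmp_path):
        from locrep.chip import load_alignments
        from locrep.formats_io import GenomeAssembly
        asm = GenomeAssembly({"chr1": random_sequence(2000, 0.5, np.random.default_rng(2))})
        model = synthetic.ChipModel("F", 1.0, 50, 100, 100)
        chip, _ = synthetic.simulate_chip_reads(asm, [], model, 4)
        path = tmp_path / "chip.sam"
        synthetic.write_sam(path, asm, chip)
        aset = load_alignments(str(path))
        assert aset.total_weighted_reads == pytest.approx(100.0)
        by_read = {}
        for rid, iv, n in aset.records:
            by_read.setdefault(rid, []).append((iv.start, n))
        orig = {rid: sorted(iv.start for iv in locs) for rid, locs in chip}
        assert {rid: sorted(s for s, _ in v) for rid, v in by_read.items()} == orig
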
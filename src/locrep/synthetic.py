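"""Synthetic genomes, annotations, reads, and ortholog sets with planted truth.

The generator emulates the statistical structure the downstream analyses
assume: loci carrying discontinuously repeating families (100-750 bp,
3-40 copies per locus), tandem arrays, interspersed TE copies, a severalfold
local-repeat burden difference between a lncRNA-like and an mRNA-like gene
class, ChIP reads enriched over input at one repeat family with multi-mapping
across its copies, and ortholog sets evolved down a known two-clade tree.

Every public entry point is deterministic given its seed: identical configs
produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import BASE_CODES, random_sequence, revcomp, seq_to_u8, u8_to_seq
from .formats_io import GenomeAssembly, GeneAnnotation, GenomicInterval

OUTSIDE_TRUNCATION = 0.6  # dispersed copies of a local family keep this prefix fraction
DISPERSAL_MIN_SEP = 250_000  # bp separation sought between outside copies


@dataclass
class PlantSpec:
    """One repeat family to plant: consensus length, copies, divergence,
    host locus behaviour."""

    family_id: str
    consensus_length: int
    copy_number: int
    divergence: float = 0.05
    indel_rate: float = 0.0
    host_locus: str | None = None  # gene_id of the host, or None => dispersed
    locality_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.copy_number < 2:
            raise ValueError(f"{self.family_id}: copy_number must be >= 2")
        if not (0 <= self.divergence < 0.5):
            raise ValueError(f"{self.family_id}: divergence must be in [0, 0.5)")
        if not (0 <= self.indel_rate < 0.5):
            raise ValueError(f"{self.family_id}: indel_rate must be in [0, 0.5)")


@dataclass
class TandemSpec:
    array_id: str
    period: int
    copy_number: int
    impurity: float = 0.0  # per-base substitution rate applied after tiling


@dataclass
class GeneClassModel:
    """Per-biotype gene counts and lengths (genes are placed, not sequenced)."""

    n_lnc: int = 13
    n_mrna: int = 5
    lnc_length: int = 15_000
    mrna_length: int = 10_000


@dataclass
class ChipModel:
    bound_family: str = "LR01"
    fold: float = 10.0
    read_length: int = 50
    n_chip: int = 20_000
    n_input: int = 20_000


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 500_000
    gc_content: float = 0.45
    planted_families: list[PlantSpec] = field(default_factory=list)
    tandem_specs: list[TandemSpec] = field(default_factory=list)
    te_library: list[tuple[str, str]] = field(default_factory=list)
    n_te_copies: int = 0
    te_divergence: float = 0.10
    gene_model: GeneClassModel = field(default_factory=GeneClassModel)
    chip_model: ChipModel = field(default_factory=ChipModel)

    def __post_init__(self) -> None:
        if not (0 <= self.gc_content <= 1):
            raise ValueError("gc_content must be in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth emitted alongside every simulated artifact."""

    instances: pd.DataFrame  # family_id, chrom, start, end, strand, identity, inside_host
    genes: pd.DataFrame  # gene_id, biotype, chrom, start, end, n_lr, n_tr
    consensi: dict[str, str]
    tandem_arrays: pd.DataFrame  # array_id, chrom, start, end, period, copy_number

    def family_instances(self, family_id: str) -> pd.DataFrame:
        return self.instances[self.instances.family_id == family_id]


# ---------------------------------------------------------------------------
# Mutation


def mutate_copy(consensus: str, divergence: float, indel_rate: float,
                rng: np.random.Generator) -> str:
    """Mutate a consensus: per-base substitutions at rate `divergence` (to a
    uniformly chosen *different* base), and single-base insertions/deletions
    each at rate `indel_rate`."""
    if not consensus:
        raise ValueError("empty consensus")
    if not (0 <= divergence < 0.5):
        raise ValueError("divergence must be in [0, 0.5)")
    if not (0 <= indel_rate < 0.5):
        raise ValueError("indel_rate must be in [0, 0.5)")
    arr = seq_to_u8(consensus).copy()
    n = arr.size
    if divergence > 0:
        hit = rng.random(n) < divergence
        idx = np.nonzero(hit)[0]
        if idx.size:
            # shift by 1..3 positions in base order => always a different base
            base_idx = np.searchsorted(BASE_CODES, arr[idx])
            new_idx = (base_idx + rng.integers(1, 4, size=idx.size)) % 4
            arr[idx] = BASE_CODES[new_idx]
    if indel_rate == 0:
        return u8_to_seq(arr)
    out: list[str] = []
    dels = rng.random(n) < indel_rate
    ins = rng.random(n + 1) < indel_rate
    ins_base = rng.choice(BASE_CODES, size=n + 1)
    for i in range(n):
        if ins[i]:
            out.append(chr(ins_base[i]))
        if not dels[i]:
            out.append(chr(arr[i]))
    if ins[n]:
        out.append(chr(ins_base[n]))
    return "".join(out)


# ---------------------------------------------------------------------------
# Placement helpers


class _Placer:
    """Rejection-sampling placement of non-overlapping intervals."""

    def __init__(self, genome_length: int, rng: np.random.Generator, max_tries: int = 2000):
        self.L = genome_length
        self.rng = rng
        self.max_tries = max_tries
        self.occupied: list[tuple[int, int]] = []

    def _clashes(self, s: int, e: int) -> bool:
        return any(s < oe and os_ < e for os_, oe in self.occupied)

    def place(self, length: int, lo: int = 0, hi: int | None = None,
              min_dist_to: Sequence[tuple[int, int]] = (), min_dist: int = 0) -> int:
        hi = self.L if hi is None else hi
        if hi - lo < length:
            raise ValueError(f"placement window [{lo},{hi}) shorter than element ({length} bp)")
        for _ in range(self.max_tries):
            s = int(self.rng.integers(lo, hi - length + 1))
            e = s + length
            if self._clashes(s, e):
                continue
            if min_dist and any(abs(s - os_) < min_dist for os_, _ in min_dist_to):
                continue
            self.occupied.append((s, e))
            return s
        raise ValueError(
            f"could not place a {length} bp element in [{lo},{hi}) after "
            f"{self.max_tries} tries (genome too crowded)")


# ---------------------------------------------------------------------------
# Genome simulation


def simulate_genome(config: SimulationConfig
                    ) -> tuple[GenomeAssembly, list[GeneAnnotation], list[GenomicInterval], TruthTable]:
    """Build one synthetic chromosome with planted repeat families, tandem
    arrays, TE copies and a two-class gene annotation.

    Background bases are i.i.d. at ``gc_content``. Planted elements never
    overlap one another. For each family, ``ceil(locality_fraction * copies)``
    copies go inside the host locus; the remainder are truncated to 60% of the
    consensus length and placed outside it, >=250 kb apart from each other
    when the genome size permits.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    planted_bp = (
        sum(s.consensus_length * s.copy_number for s in config.planted_families)
        + sum(t.period * t.copy_number for t in config.tandem_specs)
        + config.n_te_copies * (max((len(s) for _, s in config.te_library), default=0))
    )
    if planted_bp >= L:
        raise ValueError(f"planted material ({planted_bp} bp) exceeds genome length ({L} bp)")

    genome = seq_to_u8(random_sequence(L, config.gc_content, rng)).copy()
    placer = _Placer(L, rng)

    # --- genes (annotation only; two biotype classes)
    gm = config.gene_model
    gene_placer = _Placer(L, rng)  # genes must not overlap each other
    genes: list[GeneAnnotation] = []
    for i in range(gm.n_lnc):
        s = gene_placer.place(gm.lnc_length)
        genes.append(GeneAnnotation(f"lnc{i:03d}", GenomicInterval("chr1", s, s + gm.lnc_length, "+"), "lncRNA"))
    for i in range(gm.n_mrna):
        s = gene_placer.place(gm.mrna_length)
        genes.append(GeneAnnotation(f"pc{i:03d}", GenomicInterval("chr1", s, s + gm.mrna_length, "+"), "mRNA"))
    genes.sort(key=lambda g: g.interval.start)
    gene_by_id = {g.gene_id: g for g in genes}
    gene_spans = [(g.interval.start, g.interval.end) for g in genes]

    def outside_genes(s: int, e: int) -> bool:
        return not any(s < ge and gs < e for gs, ge in gene_spans)

    # --- TE copies
    te_intervals: list[GenomicInterval] = []
    if config.te_library and config.n_te_copies:
        for i in range(config.n_te_copies):
            name, cons = config.te_library[i % len(config.te_library)]
            copy = mutate_copy(cons, config.te_divergence, 0.0, rng)
            s = placer.place(len(copy))
            genome[s:s + len(copy)] = seq_to_u8(copy)
            te_intervals.append(GenomicInterval("chr1", s, s + len(copy), "+", name))
    te_intervals.sort()

    # --- tandem arrays
    tandem_rows = []
    for spec in config.tandem_specs:
        motif = random_sequence(spec.period, config.gc_content, rng)
        array = mutate_copy(motif * spec.copy_number, spec.impurity, 0.0, rng)
        s = placer.place(len(array))
        genome[s:s + len(array)] = seq_to_u8(array)
        tandem_rows.append(dict(array_id=spec.array_id, chrom="chr1", start=s, end=s + len(array),
                                period=spec.period, copy_number=spec.copy_number, motif=motif))

    # --- repeat families
    consensi: dict[str, str] = {}
    inst_rows = []
    for spec in config.planted_families:
        cons = random_sequence(spec.consensus_length, config.gc_content, rng)
        consensi[spec.family_id] = cons
        if spec.host_locus is not None:
            n_inside = math.ceil(spec.locality_fraction * spec.copy_number)
            host = gene_by_id[spec.host_locus]
            lo, hi = host.interval.start, host.interval.end
        else:
            n_inside = 0
            lo = hi = None
        outside_placed: list[tuple[int, int]] = []
        for ci in range(spec.copy_number):
            inside = ci < n_inside
            if inside:
                seq = mutate_copy(cons, spec.divergence, spec.indel_rate, rng)
            else:
                trunc = cons[: max(1, int(OUTSIDE_TRUNCATION * len(cons)))]
                seq = mutate_copy(trunc, spec.divergence, spec.indel_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placed_seq = seq if strand == "+" else revcomp(seq)
            if inside:
                s = placer.place(len(placed_seq), lo, hi)
            else:
                s = _place_outside(placer, len(placed_seq), lo, hi, outside_placed,
                                   outside_ok=outside_genes if spec.host_locus is None else None)
                outside_placed.append((s, s + len(placed_seq)))
            genome[s:s + len(placed_seq)] = seq_to_u8(placed_seq)
            ident = _identity_to_consensus(seq, cons if inside else cons[: len(seq)])
            inst_rows.append(dict(family_id=spec.family_id, chrom="chr1", start=s,
                                  end=s + len(placed_seq), strand=strand,
                                  identity=ident, inside_host=inside,
                                  host=spec.host_locus or ""))

    assembly = GenomeAssembly({"chr1": u8_to_seq(genome)})
    instances = pd.DataFrame(inst_rows).sort_values(["family_id", "start"]).reset_index(drop=True)
    tandems = pd.DataFrame(tandem_rows, columns=["array_id", "chrom", "start", "end",
                                                 "period", "copy_number", "motif"])

    gene_rows = []
    for g in genes:
        if len(instances):
            in_gene = instances[(instances.start >= g.interval.start) & (instances.end <= g.interval.end)]
            n_lr = int(len(in_gene))
        else:
            n_lr = 0
        n_tr = int(((tandems.start < g.interval.end) & (tandems.end > g.interval.start)).sum()) if len(tandems) else 0
        gene_rows.append(dict(gene_id=g.gene_id, biotype=g.biotype, chrom=g.interval.chrom,
                              start=g.interval.start, end=g.interval.end, n_lr=n_lr, n_tr=n_tr))
    truth = TruthTable(instances, pd.DataFrame(gene_rows), consensi, tandems)
    return assembly, genes, te_intervals, truth


def _place_outside(placer: _Placer, length: int, host_lo, host_hi,
                   already: list[tuple[int, int]], outside_ok=None) -> int:
    """Place an outside copy: away from the host locus, >=250 kb from the other
    outside copies when feasible, falling back to plain non-overlap."""
    for min_dist in (DISPERSAL_MIN_SEP, 0):
        for _ in range(placer.max_tries):
            s = int(placer.rng.integers(0, placer.L - length + 1))
            e = s + length
            if host_lo is not None and s < host_hi and host_lo < e:
                continue
            if placer._clashes(s, e):
                continue
            if outside_ok is not None and not outside_ok(s, e):
                continue
            if min_dist and any(abs(s - os_) < min_dist for os_, _ in already):
                continue
            placer.occupied.append((s, e))
            return s
    raise ValueError(f"could not place outside copy of {length} bp")


def _identity_to_consensus(seq: str, cons: str) -> float:
    if len(seq) == len(cons):
        a, b = seq_to_u8(seq), seq_to_u8(cons)
        return float((a == b).mean())
    import edlib
    res = edlib.align(seq, cons, task="distance")
    return 1.0 - res["editDistance"] / max(len(seq), len(cons))


# ---------------------------------------------------------------------------
# Presets

_FIRRE_LENGTHS = [100, 115, 130, 150, 160, 165, 167, 180, 220, 300, 420, 600, 750]
_FIRRE_COPIES = [40, 32, 25, 20, 16, 14, 12, 11, 10, 9, 7, 5, 3]
_FIRRE_DIVERGENCE = [0.02, 0.05, 0.08, 0.10]


def firre_like_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions: 500 kb genome, 13 local families
    (median length 167 bp, median 12 copies, <=10% divergence), 8 fully local
    + 5 predominantly local families, 2 dispersed families, 5 tandem arrays,
    20 TE copies, 13 lncRNA-like host genes and 5 mRNA-like genes."""
    rng = np.random.default_rng(seed + 10_007)  # TE library stream
    fams = []
    for i, (ln, cp) in enumerate(zip(_FIRRE_LENGTHS, _FIRRE_COPIES)):
        fams.append(PlantSpec(
            family_id=f"LR{i:02d}",
            consensus_length=ln,
            copy_number=cp,
            divergence=_FIRRE_DIVERGENCE[i % len(_FIRRE_DIVERGENCE)],
            host_locus=f"lnc{i:03d}",
            locality_fraction=0.85 if cp >= 14 else 1.0,
        ))
    fams.append(PlantSpec("DISP00", 150, 8, divergence=0.05, host_locus=None))
    fams.append(PlantSpec("DISP01", 200, 6, divergence=0.05, host_locus=None))
    tandems = [TandemSpec(f"TA{i:02d}", p, c, impurity=0.02)
               for i, (p, c) in enumerate([(3, 60), (8, 30), (25, 14), (60, 8), (120, 5)])]
    te_lib = [(f"TE{i}", random_sequence(500, 0.42, rng)) for i in range(2)]
    return SimulationConfig(
        seed=seed, genome_length=500_000, gc_content=0.45,
        planted_families=fams, tandem_specs=tandems,
        te_library=te_lib, n_te_copies=20,
        gene_model=GeneClassModel(n_lnc=13, n_mrna=5),
        chip_model=ChipModel(bound_family="LR00", fold=10.0),
    )


def demo_config(seed: int = 0) -> SimulationConfig:
    """A small, fast preset (60 kb, 4 local families) for smoke tests and
    determinism checks."""
    rng = np.random.default_rng(seed + 10_007)
    fams = [
        PlantSpec("LR00", 120, 10, divergence=0.03, host_locus="lnc000"),
        PlantSpec("LR01", 150, 8, divergence=0.05, host_locus="lnc001"),
        PlantSpec("LR02", 200, 6, divergence=0.08, host_locus="lnc002"),
        PlantSpec("LR03", 300, 4, divergence=0.05, host_locus="lnc003"),
        PlantSpec("DISP00", 150, 5, divergence=0.05, host_locus=None),
    ]
    tandems = [TandemSpec("TA00", 4, 40, impurity=0.02), TandemSpec("TA01", 30, 8, impurity=0.02)]
    te_lib = [("TE0", random_sequence(400, 0.42, rng))]
    return SimulationConfig(
        seed=seed, genome_length=60_000, gc_content=0.45,
        planted_families=fams, tandem_specs=tandems,
        te_library=te_lib, n_te_copies=6,
        gene_model=GeneClassModel(n_lnc=4, n_mrna=2, lnc_length=6000, mrna_length=5000),
        chip_model=ChipModel(bound_family="LR00", fold=10.0, n_chip=4000, n_input=4000),
    )


PRESETS = {"firre_like": firre_like_config, "demo": demo_config}


# ---------------------------------------------------------------------------
# ChIP read simulation


def simulate_chip_reads(genome: GenomeAssembly, bound_regions: list[GenomicInterval],
                        chip_model: ChipModel, seed: int
                        ) -> tuple[list[tuple[str, list[GenomicInterval]]],
                                   list[tuple[str, list[GenomicInterval]]]]:
    """Simulate ChIP and input read *alignments* over a genome.

    Input read starts are uniform over the genome; ChIP read starts are
    uniform except for a ``fold`` multiplier over the bound family's
    instances. Each read is reported at every genomic position whose sequence
    is within 1 mismatch of the read (so reads from near-identical repeat
    copies multi-map); returned records carry all reported locations.

    Returns (chip, input) as lists of (read_id, [locations]).
    """
    rng = np.random.default_rng(seed)
    chrom = next(iter(genome.sequences))
    seq = genome.sequences[chrom]
    arr = seq_to_u8(seq)
    L = len(seq)
    rl = chip_model.read_length
    if bound_regions and rl > min(len(iv) for iv in bound_regions):
        import logging
        logging.getLogger(__name__).warning(
            "read length %d exceeds the shortest bound instance", rl)

    n_starts = L - rl + 1
    bound_mask = np.zeros(n_starts, dtype=bool)
    for iv in bound_regions:
        lo = max(0, iv.start - rl + 1)
        hi = min(n_starts, iv.end)
        bound_mask[lo:hi] = True
    n_f = int(bound_mask.sum())
    fold = chip_model.fold
    # background start weight chosen so the ChIP/input coverage ratio over
    # the bound instances equals `fold` (on a finite genome a plain fold
    # multiplier is diluted by its own contribution to the library)
    bg = (n_starts - fold * n_f) / (n_starts - n_f) if n_starts > n_f else 1.0
    if bg <= 0:
        import logging
        logging.getLogger(__name__).warning(
            "fold %g over %d/%d start positions saturates the library; "
            "enrichment will fall short of the requested fold", fold, n_f, n_starts)
        bg = 0.01
    weights = np.where(bound_mask, fold, bg)
    p_chip = weights / weights.sum()

    index = _HalfIndex(arr, rl)

    def draw(n: int, p: np.ndarray | None, prefix: str) -> list[tuple[str, list[GenomicInterval]]]:
        starts = rng.choice(n_starts, size=n, p=p)
        out = []
        for i, s in enumerate(starts):
            read = arr[s:s + rl]
            locs = index.placements(read)
            ivs = [GenomicInterval(chrom, int(q), int(q) + rl, "+") for q in locs]
            out.append((f"{prefix}{i:06d}", ivs))
        return out

    chip = draw(chip_model.n_chip, p_chip, "c")
    inp = draw(chip_model.n_input, None, "i")
    return chip, inp


class _HalfIndex:
    """Find all genomic placements of a read within 1 mismatch, by the
    pigeonhole principle: a <=1-mismatch occurrence matches at least one of the
    two read halves exactly."""

    def __init__(self, genome: np.ndarray, read_length: int):
        self.arr = genome
        self.rl = read_length
        self.h = read_length // 2
        self.left: dict[bytes, list[int]] = {}
        self.right: dict[bytes, list[int]] = {}
        g = genome.tobytes()
        for i in range(len(genome) - read_length + 1):
            self.left.setdefault(g[i:i + self.h], []).append(i)
            self.right.setdefault(g[i + self.h:i + read_length], []).append(i)

    def placements(self, read: np.ndarray) -> list[int]:
        b = read.tobytes()
        cands = set(self.left.get(b[:self.h], ())) | set(self.right.get(b[self.h:], ()))
        out = []
        for s in cands:
            if int(np.count_nonzero(self.arr[s:s + self.rl] != read)) <= 1:
                out.append(s)
        return sorted(out)


def write_sam(path: str | Path, genome: GenomeAssembly,
              reads: list[tuple[str, list[GenomicInterval]]]) -> None:
    """Write multi-mapped read records as plain-text SAM; the NH tag carries
    the number of reported locations for the read."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in genome.lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for read_id, locs in reads:
            nh = len(locs)
            for k, iv in enumerate(locs):
                flag = 0 if k == 0 else 256  # secondary for extra placements
                seq = genome.fetch(iv.chrom, iv.start, iv.end)
                fh.write(f"{read_id}\t{flag}\t{iv.chrom}\t{iv.start + 1}\t"
                         f"{0 if nh > 1 else 60}\t{len(iv)}M\t*\t0\t0\t{seq}\t*\tNH:i:{nh}\n")


# ---------------------------------------------------------------------------
# Ortholog simulation (Jukes-Cantor down a tree)


def simulate_ortholog_set(tree_newick: str, root_sequence: str, seed: int) -> dict[str, str]:
    """Evolve ``root_sequence`` down a newick tree under Jukes-Cantor.

    Branch lengths are expected substitutions/site; per-branch substitution
    probability is p = 3/4 * (1 - exp(-4 b / 3)). Returns one sequence per
    leaf. No indels are modelled.
    """
    from .phylo import parse_newick  # local import: phylo depends on formats only

    root = parse_newick(tree_newick)
    rng = np.random.default_rng(seed)
    leaves: dict[str, str] = {}
    root_arr = seq_to_u8(root_sequence)

    def walk(node, arr: np.ndarray) -> None:
        for child, blen in node.children:
            if blen < 0:
                raise ValueError(f"negative branch length {blen}")
            p = 0.75 * (1.0 - math.exp(-4.0 * blen / 3.0))
            child_arr = arr.copy()
            hit = rng.random(arr.size) < p
            idx = np.nonzero(hit)[0]
            if idx.size:
                base_idx = np.searchsorted(BASE_CODES, child_arr[idx])
                new_idx = (base_idx + rng.integers(1, 4, size=idx.size)) % 4
                child_arr[idx] = BASE_CODES[new_idx]
            if child.children:
                walk(child, child_arr)
            else:
                leaves[child.label] = u8_to_seq(child_arr)
        if not node.children:
            leaves[node.label] = u8_to_seq(arr)

    walk(root, root_arr)
    return leaves


# ---------------------------------------------------------------------------
# Count-level burden simulation (for the rank-sum power/calibration regime)


def simulate_burden_counts(n_genes: int, rate_per_100kb: float, tr_rate_per_100kb: float,
                           rng: np.random.Generator,
                           mean_length: float = 30_000, sd_log10: float = 0.25
                           ) -> pd.DataFrame:
    """Per-gene repeat counts for one gene class: lengths log-normal around
    ``mean_length``, LR and TR counts Poisson at the given per-100 kb rates.

    Returns a frame with gene lengths (bp), counts, and per-kb burdens.
    """
    lengths = 10 ** rng.normal(math.log10(mean_length), sd_log10, size=n_genes)
    lengths = np.maximum(lengths, 1000.0)
    n_lr = rng.poisson(rate_per_100kb * lengths / 100_000)
    n_tr = rng.poisson(tr_rate_per_100kb * lengths / 100_000)
    return pd.DataFrame(dict(
        length=lengths, n_lr=n_lr, n_tr=n_tr,
        lr_per_kb=n_lr / (lengths / 1000), tr_per_kb=n_tr / (lengths / 1000)))


def write_truth(outdir: str | Path, truth: TruthTable) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.instances.to_csv(outdir / "truth_instances.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.tandem_arrays.to_csv(outdir / "truth_tandems.tsv", sep="\t", index=False)
    from .formats_io import write_fasta
    if truth.consensi:
        write_fasta(outdir / "truth_consensi.fa", truth.consensi)
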
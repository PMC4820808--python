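"""De-novo discovery of repeated substrings by k-mer seeding and greedy
bidirectional consensus extension on a TE-masked genome.

The discovery model: every exact k-mer (default k=16) occurring at least
``min_count`` times seeds a candidate family; occurrences are pooled across
strands under the canonical (lexicographically smaller) form of the k-mer.
Seeds are processed in descending occurrence order and extended one column at
a time in each direction. At each column the consensus base is the majority
base over the live copies; the column contributes
``n_agree - n_disagree - c`` to a running score (c is the consensus-length
penalty of the objective, default 2), and extension in a direction stops when
the running score falls more than ``x_drop`` below its maximum. Copies whose
identity to the growing consensus drops below ``min_identity`` leave the live
set. The consensus is trimmed to the maximum-scoring extent. Genome positions
claimed by an accepted family are tombstoned so later seeds cannot
re-discover the same element.

Folding the length penalty into the running score is what makes background
extension terminate at small copy numbers: the expected raw majority-vote
column score over random sequence is positive for n <= 7 copies (e.g. +0.375
at n=3), so an unpenalized X-drop would never trigger there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seq import canonical_kmer, seq_to_u8, u8_to_seq, BASE_CODES
from .formats_io import GenomeAssembly, GenomicInterval

log = logging.getLogger(__name__)

_N = ord("N")


@dataclass
class MaskedGenome:
    """Assembly with TE positions set to N, plus the mask that produced it."""

    assembly: GenomeAssembly
    masked_intervals: list[GenomicInterval]
    source: str = "TE_annotation"


@dataclass
class SeedFamily:
    kmer: str  # canonical form
    occurrences: list[tuple[str, int, str]]  # (chrom, position, strand)

    @property
    def count(self) -> int:
        return len(self.occurrences)


@dataclass
class RepeatFamily:
    family_id: str
    consensus: str
    instances: list[tuple[GenomicInterval, float]]  # (interval, identity)
    objective_score: float = 0.0

    @property
    def n_instances(self) -> int:
        return len(self.instances)


@dataclass
class DiscoveryParams:
    k: int = 16
    min_count: int = 3
    min_identity: float = 0.8
    x_drop: float = 20.0
    length_penalty: float = 2.0  # c in the objective score
    min_length: int = 50
    max_extend: int = 2000  # per direction, bp


# ---------------------------------------------------------------------------


def mask_te(assembly: GenomeAssembly, te_intervals: list[GenomicInterval]) -> MaskedGenome:
    """Replace bases inside the TE intervals by N (union semantics); the input
    assembly is left untouched."""
    masked: dict[str, str] = {}
    arrays = {name: seq_to_u8(seq).copy() for name, seq in assembly.sequences.items()}
    n_masked = 0
    for iv in te_intervals:
        if iv.chrom not in arrays:
            raise ValueError(f"interval on unknown sequence {iv.chrom!r}")
        if iv.end > arrays[iv.chrom].size:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} off the chromosome end")
        arrays[iv.chrom][iv.start:iv.end] = _N
    for name, arr in arrays.items():
        n_masked += int((arr == _N).sum())
        masked[name] = u8_to_seq(arr)
    total = sum(assembly.lengths.values())
    log.info("masked %d/%d bp (%.2f%%)", n_masked, total, 100 * n_masked / total)
    return MaskedGenome(GenomeAssembly(masked), sorted(te_intervals))


def find_seeds(masked: MaskedGenome, k: int = 16, min_count: int = 3) -> list[SeedFamily]:
    """All k-mers occurring >= min_count times, with forward and
    reverse-complement occurrences pooled under the canonical k-mer.
    Families sorted by descending occurrence count (kmer as tie-break)."""
    if k < 8:
        raise ValueError("k must be >= 8")
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    counts: dict[str, list[tuple[str, int, str]]] = {}
    any_long_enough = False
    for chrom, seq in masked.assembly.sequences.items():
        if len(seq) < k:
            continue
        any_long_enough = True
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            canon, strand = canonical_kmer(kmer)
            counts.setdefault(canon, []).append((chrom, i, strand))
    if not any_long_enough:
        log.warning("k=%d exceeds every sequence length; no seeds", k)
        return []
    fams = [SeedFamily(kmer, occ) for kmer, occ in counts.items() if len(occ) >= min_count]
    fams.sort(key=lambda f: (-f.count, f.kmer))
    return fams


# ---------------------------------------------------------------------------
# Extension


class _CopyWindows:
    """Oriented genome windows around each seed occurrence.

    Column coordinates: column j (can be negative) maps to position
    seed_start + j in the oriented frame; the seed occupies columns
    [0, k). Off-genome columns read as N.
    """

    def __init__(self, masked: MaskedGenome, occurrences, k: int, max_extend: int):
        self.k = k
        self.w = max_extend
        self.windows: list[np.ndarray] = []
        self.origins = occurrences
        for chrom, pos, strand in occurrences:
            seq = masked.assembly.sequences[chrom]
            lo, hi = pos - max_extend, pos + k + max_extend
            pad_l, pad_r = max(0, -lo), max(0, hi - len(seq))
            chunk = seq_to_u8(seq[max(0, lo):min(len(seq), hi)])
            if pad_l or pad_r:
                chunk = np.concatenate([np.full(pad_l, _N, np.uint8), chunk,
                                        np.full(pad_r, _N, np.uint8)])
            if strand == "-":
                from ._seq import revcomp_u8
                chunk = revcomp_u8(chunk)
            self.windows.append(chunk)
        self.mat = np.stack(self.windows)  # (n_copies, k + 2*max_extend)

    def column(self, j: int) -> np.ndarray:
        return self.mat[:, self.w + j]

    def genomic_interval(self, copy_idx: int, left: int, right: int) -> GenomicInterval:
        """Interval covering oriented columns [-left, k+right) for one copy."""
        chrom, pos, strand = self.origins[copy_idx]
        if strand == "+":
            s, e = pos - left, pos + self.k + right
        else:
            s, e = pos - right, pos + self.k + left
        return GenomicInterval(chrom, max(0, s), e, strand)


def extend_seed(masked: MaskedGenome, seed: SeedFamily,
                params: DiscoveryParams | None = None) -> RepeatFamily | None:
    """Extend one seed family into a repeat family, or None if degenerate."""
    params = params or DiscoveryParams()
    k = len(seed.kmer)
    if seed.count < params.min_count:
        return None
    cw = _CopyWindows(masked, seed.occurrences, k, params.max_extend)
    n = seed.count
    live = np.ones(n, dtype=bool)
    # identity bookkeeping: matches over extended columns; seed columns match
    # by construction (exact k-mer)
    matches = np.full(n, float(k))
    columns = float(k)

    def extend(direction: int) -> tuple[int, list[int]]:
        """direction -1 = leftward (columns -1, -2, ...), +1 = rightward
        (columns k, k+1, ...). Returns (extent, consensus codes outward)."""
        nonlocal columns
        run, best, extent = 0.0, 0.0, 0
        cons: list[int] = []
        for step in range(1, params.max_extend + 1):
            j = -step if direction < 0 else k - 1 + step
            if not live.any():
                break
            col = cw.column(j)[live]
            valid = col != _N
            if not valid.any():
                break
            cnt = np.bincount(col[valid], minlength=256)[BASE_CODES]
            best_base = BASE_CODES[int(np.argmax(cnt))]  # argmax -> alphabetical tie-break
            n_agree = int(cnt.max())
            n_disagree = int(valid.sum()) - n_agree
            run += n_agree - n_disagree - params.length_penalty
            cons.append(int(best_base))
            full_col = cw.column(j)
            matches[live] += (full_col[live] == best_base).astype(float)
            columns += 1.0
            # drop copies falling below the identity floor
            live[live & (matches / columns < params.min_identity)] = False
            if run > best:
                best, extent = run, step
            if run < best - params.x_drop:
                break
        return extent, cons

    left_extent, left_cons = extend(-1)
    right_extent, right_cons = extend(+1)
    if not live.any():
        log.info("seed %s: all copies dropped during extension", seed.kmer)
        return None

    consensus = (u8_to_seq(np.array(left_cons[:left_extent][::-1], dtype=np.uint8))
                 + seed.kmer
                 + u8_to_seq(np.array(right_cons[:right_extent], dtype=np.uint8)))
    cons_arr = seq_to_u8(consensus)

    # final per-copy identity over the trimmed extent
    instances: list[tuple[GenomicInterval, float]] = []
    per_copy_scores = []
    lens = masked.assembly.lengths
    for ci in np.nonzero(live)[0]:
        window = cw.mat[ci, cw.w - left_extent: cw.w + k + right_extent]
        m = int((window == cons_arr).sum())
        ident = m / len(consensus)
        if ident < params.min_identity:
            continue
        iv = cw.genomic_interval(int(ci), left_extent, right_extent)
        chrom_len = lens[iv.chrom]
        iv = GenomicInterval(iv.chrom, max(0, iv.start), min(chrom_len, iv.end), iv.strand)
        instances.append((iv, ident))
        per_copy_scores.append(m - (len(consensus) - m))
    instances = _dedupe_instances(instances)
    if len(instances) < 2:
        return None
    objective = float(sum(per_copy_scores) - params.length_penalty * len(consensus))
    return RepeatFamily("", consensus, instances, objective)


def _dedupe_instances(instances):
    """Merge instances overlapping >50% reciprocally, keeping the best identity."""
    out: list[tuple[GenomicInterval, float]] = []
    for iv, ident in sorted(instances, key=lambda t: (t[0].chrom, t[0].start, -t[1])):
        if out:
            prev, pident = out[-1]
            ov = prev.overlap(iv)
            if ov > 0.5 * min(len(prev), len(iv)):
                if ident > pident:
                    out[-1] = (iv, ident)
                continue
        out.append((iv, ident))
    return out


# ---------------------------------------------------------------------------
# Whole-genome discovery


def discover_repeats(masked: MaskedGenome, params: DiscoveryParams | None = None
                     ) -> list[RepeatFamily]:
    """Run seeded extension over the whole masked genome with tombstoning.

    Seeds are processed in descending occurrence order; positions claimed by
    an accepted family are tombstoned so later seeds cannot re-discover the
    same element. Because exact k-mer seeds miss diverged copies (an intact
    shared 16-mer survives in a copy with probability (1-d)^16), each
    accepted consensus is mapped back over the unclaimed genome to complete
    its instance set before tombstoning. Families with < 2 surviving
    instances or consensus shorter than ``min_length`` are discarded.
    Deterministic given its input.
    """
    params = params or DiscoveryParams()
    seeds = find_seeds(masked, params.k, params.min_count)
    claimed = {name: np.zeros(length, dtype=bool)
               for name, length in masked.assembly.lengths.items()}
    families: list[RepeatFamily] = []
    mapper = None
    for seed in seeds:
        k = len(seed.kmer)
        free = [(c, p, s) for c, p, s in seed.occurrences if not claimed[c][p:p + k].any()]
        if len(free) < params.min_count:
            continue
        fam = extend_seed(masked, SeedFamily(seed.kmer, free), params)
        if fam is None or len(fam.consensus) < params.min_length:
            continue
        if mapper is None:
            from .locality import ConsensusMapper, MappingParams
            mapper = ConsensusMapper(masked.assembly, MappingParams(
                min_identity=params.min_identity))
        fam.instances = _complete_instances(fam, mapper, claimed)
        if len(fam.instances) < 2:
            continue
        fam.family_id = f"F{len(families):04d}"
        for iv, _ in fam.instances:
            claimed[iv.chrom][iv.start:iv.end] = True
        families.append(fam)
    return families


def _complete_instances(fam: RepeatFamily, mapper, claimed: dict[str, np.ndarray]):
    """Map the consensus back over the genome; keep hits on unclaimed space,
    merged with the extension's own instances."""
    try:
        hits = mapper.map(fam.consensus)
    except ValueError:  # consensus shorter than the mapper's seed span
        return fam.instances
    merged = dict()
    for iv, ident in fam.instances + hits:
        if claimed[iv.chrom][iv.start:iv.end].sum() > 0.5 * len(iv):
            continue
        merged.setdefault((iv.chrom, iv.start // 20), []).append((iv, ident))
    return _dedupe_instances([t for group in merged.values() for t in group])
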
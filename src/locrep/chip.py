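"""Multi-mapping-aware ChIP-Seq coverage and permutation-calibrated
enrichment testing over repeat-family instances.

Reads aligning to n genomic locations are counted 1/n at each location, with
n capped at the 20 best alignments per read (ties broken by coordinate
order), so a read from a 20-copy repeat family contributes 1/20 per copy and
exactly 1 in total. Coverage over a region set is the mean weighted depth
over the union of region bases, scaled per million weighted reads so unequal
library depths cannot masquerade as enrichment. Enrichment is the ratio of
ChIP to input coverage (pseudocount 0.1 per-million units on both), its
significance assessed against a Poisson null whose rate is the mean
enrichment of 100 random equal-length-multiset region sets drawn from
non-N genome space; because the Poisson is discrete and the enrichment
continuous, the upper tail is evaluated at ceil(observed), which is
conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy import stats

from .formats_io import GenomeAssembly, GenomicInterval

log = logging.getLogger(__name__)

PSEUDOCOUNT = 0.1  # per-million units, both numerator and denominator


@dataclass
class WeightedAlignmentSet:
    """Alignment records with per-location fractional weights (1/n, n <= cap)."""

    records: list[tuple[str, GenomicInterval, int]]  # (read_id, location, n_reported)
    reference_lengths: dict[str, int]
    cap: int = 20
    total_weighted_reads: float = field(init=False)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for read_id, _, n in self.records:
            if n < 1:
                raise ValueError(f"read {read_id}: n_reported < 1")
            seen[read_id] = n
        # each read contributes (records kept / n_reported); with n_reported
        # set to the kept count this is exactly 1 per read — computed as a
        # single division so the weight sum is exact
        kept: dict[str, int] = {}
        for read_id, _, _ in self.records:
            kept[read_id] = kept.get(read_id, 0) + 1
        self.total_weighted_reads = float(sum(kept[r] / n for r, n in seen.items()))
        self._depth: dict[str, np.ndarray] | None = None

    def weight(self, record_idx: int) -> float:
        return 1.0 / self.records[record_idx][2]

    def depth_arrays(self) -> dict[str, np.ndarray]:
        """Per-chromosome raw weighted depth (lazy, cached)."""
        if self._depth is None:
            depth = {c: np.zeros(L + 1) for c, L in self.reference_lengths.items()}
            for _, iv, n in self.records:
                d = depth[iv.chrom]
                d[iv.start] += 1.0 / n
                d[iv.end] -= 1.0 / n
            self._depth = {c: np.cumsum(d[:-1]) for c, d in depth.items()}
        return self._depth


def from_multimapped_reads(reads: list[tuple[str, list[GenomicInterval]]],
                           reference_lengths: dict[str, int], cap: int = 20
                           ) -> WeightedAlignmentSet:
    """Build a weighted set from in-memory (read_id, locations) records,
    applying the best-``cap`` rule (all placements score equally here, so the
    tie-break is coordinate order)."""
    records = []
    for read_id, locs in reads:
        if not locs:
            continue
        kept = sorted(locs, key=lambda iv: (iv.chrom, iv.start))[:cap]
        for iv in kept:
            records.append((read_id, iv, len(kept)))
    return WeightedAlignmentSet(records, reference_lengths, cap)


def load_alignments(path: str, cap: int = 20) -> WeightedAlignmentSet:
    """Load a SAM/BAM file into a :class:`WeightedAlignmentSet`.

    Records of one read are grouped by read name (input need not be sorted).
    If a read has more than ``cap`` records the ``cap`` best by alignment
    score (AS tag; fewer mismatches via NM as fallback) are kept, ties broken
    by coordinate order, and n_reported becomes the kept count.
    """
    by_read: dict[str, list[tuple[float, str, int, int]]] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        ref_lengths = dict(zip(fh.references, fh.lengths))
        for idx, rec in enumerate(fh):
            if rec.is_unmapped:
                continue
            if rec.reference_name is None or rec.reference_start is None:
                raise ValueError(f"malformed record at index {idx}")
            if rec.has_tag("AS"):
                score = float(rec.get_tag("AS"))
            elif rec.has_tag("NM"):
                score = -float(rec.get_tag("NM"))
            else:
                score = 0.0
            by_read.setdefault(rec.query_name, []).append(
                (score, rec.reference_name, rec.reference_start, rec.reference_end))
    records = []
    for read_id in by_read:
        alns = by_read[read_id]
        alns.sort(key=lambda t: (-t[0], t[1], t[2]))
        kept = alns[:cap]
        for _, chrom, s, e in kept:
            records.append((read_id, GenomicInterval(chrom, s, e), len(kept)))
    return WeightedAlignmentSet(records, ref_lengths, cap)


# ---------------------------------------------------------------------------
# Coverage and enrichment


def weighted_coverage(alignments: WeightedAlignmentSet,
                      regions: list[GenomicInterval]) -> float:
    """Mean weighted depth over the union of region bases, scaled by
    1e6 / total weighted reads."""
    if not regions:
        raise ValueError("empty region list")
    depth = alignments.depth_arrays()
    total, n_bases = 0.0, 0
    for chrom, spans in _union_spans(regions).items():
        if chrom not in depth:
            raise ValueError(f"region on unknown reference {chrom!r}")
        d = depth[chrom]
        for s, e in spans:
            if e > d.size:
                raise ValueError(f"region {chrom}:{s}-{e} outside reference bounds")
            total += float(d[s:e].sum())
            n_bases += e - s
    mean_depth = total / n_bases
    if alignments.total_weighted_reads == 0:
        return 0.0
    return mean_depth * 1e6 / alignments.total_weighted_reads


def _union_spans(regions: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in regions:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, spans in by.items():
        spans.sort()
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [tuple(x) for x in merged]
    return out


def enrichment_score(chip: WeightedAlignmentSet, inp: WeightedAlignmentSet,
                     regions: list[GenomicInterval]) -> float:
    """ChIP/input coverage ratio with the pseudocount on both sides."""
    c = weighted_coverage(chip, regions)
    i = weighted_coverage(inp, regions)
    return (c + PSEUDOCOUNT) / (i + PSEUDOCOUNT)


@dataclass
class EnrichmentResult:
    family_id: str
    chip_cov: float
    input_cov: float
    enrichment: float
    perm_scores: np.ndarray
    lam: float
    p_value: float


def permutation_poisson_test(family_id: str, regions: list[GenomicInterval],
                             assembly: GenomeAssembly,
                             chip: WeightedAlignmentSet, inp: WeightedAlignmentSet,
                             n_perm: int = 100, seed: int = 0) -> EnrichmentResult:
    """Permutation-calibrated Poisson test of ChIP enrichment at a region set.

    Each permutation draws an equal-count, equal-length-multiset random
    region set from non-N genome space (permutation i from seed + i) and
    scores it identically to the observed regions. The mean permuted
    enrichment is the Poisson rate; p = P(X >= ceil(observed)).
    """
    if n_perm < 10:
        raise ValueError("n_perm < 10: the Poisson rate estimate is unstable")
    chip_cov = weighted_coverage(chip, regions)
    input_cov = weighted_coverage(inp, regions)
    observed = (chip_cov + PSEUDOCOUNT) / (input_cov + PSEUDOCOUNT)

    allowed = _non_n_spans(assembly)
    lengths = [len(iv) for iv in regions]
    perm_scores = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng(seed + i)
        perm_regions = _draw_regions(lengths, allowed, rng)
        perm_scores[i] = enrichment_score(chip, inp, perm_regions)
    lam = float(perm_scores.mean())
    p = float(stats.poisson.sf(int(np.ceil(observed)) - 1, lam))
    return EnrichmentResult(family_id, chip_cov, input_cov, float(observed),
                            perm_scores, lam, p)


def _non_n_spans(assembly: GenomeAssembly) -> list[tuple[str, int, int]]:
    from ._seq import seq_to_u8
    spans = []
    for chrom, seq in assembly.sequences.items():
        arr = seq_to_u8(seq) != ord("N")
        edges = np.flatnonzero(np.diff(np.concatenate([[0], arr.view(np.int8), [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            spans.append((chrom, int(a), int(b)))
    return spans


def _draw_regions(lengths: list[int], allowed: list[tuple[str, int, int]],
                  rng: np.random.Generator, max_tries: int = 1000) -> list[GenomicInterval]:
    weights = np.array([e - s for _, s, e in allowed], dtype=float)
    weights /= weights.sum()
    out: list[GenomicInterval] = []
    for L in lengths:
        for _ in range(max_tries):
            k = rng.choice(len(allowed), p=weights)
            chrom, s0, e0 = allowed[k]
            if e0 - s0 < L:
                continue
            s = int(rng.integers(s0, e0 - L + 1))
            out.append(GenomicInterval(chrom, s, s + L))
            break
        else:
            raise ValueError(f"could not place a {L} bp permutation window")
    return out


def export_bedgraph(path: str, alignments: WeightedAlignmentSet) -> None:
    """Weighted raw depth as bedGraph text (runs of constant depth)."""
    with open(path, "w") as fh:
        for chrom in sorted(alignments.reference_lengths):
            d = alignments.depth_arrays()[chrom]
            if d.size == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [d.size]])
            for s, e in zip(starts, ends):
                v = d[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
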
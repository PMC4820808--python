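"""Genome-wide consensus mapping and locality classification.

A *local* repeat family concentrates its genomic instances inside one host
locus: the call is LOCAL when at least ``locality_min`` (default 0.8, the
operational form of the "at least 80% within the locus" summary) of its
mapped instances fall inside a single annotated gene span (introns included).
Outside instances carry two descriptive dispersal diagnostics — whether they
are shorter than the in-locus median instance length, and whether outside
instances sit more than 250 kb from their nearest outside neighbour — which
are recorded as flags, never used to veto a LOCAL call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._seq import revcomp
from .formats_io import GenomeAssembly, GeneAnnotation, GenomicInterval

log = logging.getLogger(__name__)

DISPERSAL_DISTANCE = 250_000  # bp; the outside-instance separation diagnostic


@dataclass
class MappingParams:
    k_map: int = 12
    min_identity: float = 0.7
    min_length_fraction: float = 0.5  # of consensus length
    cluster_gap_factor: float = 2.0  # cluster break at gap > factor * consensus len


@dataclass
class OutsideFlags:
    interval: GenomicInterval
    shorter_than_locus_median: bool
    nearest_outside_neighbor_distance: int | None  # None when it is the only one


@dataclass
class LocalityCall:
    family_id: str
    call: str  # LOCAL | DISPERSED
    host_locus: str | None
    locality_fraction: float
    n_instances: int
    outside_flags: list[OutsideFlags] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.call not in ("LOCAL", "DISPERSED"):
            raise ValueError(f"invalid call {self.call!r}")
        if (self.host_locus is not None) != (self.call == "LOCAL"):
            raise ValueError("host_locus must be set iff call is LOCAL")


@dataclass
class LocalityParams:
    locality_min: float = 0.8
    inside_fraction: float = 0.5  # instance counted inside if >=50% bases overlap
    flank: int = 0  # bp added to each gene span


# ---------------------------------------------------------------------------
# Consensus mapping


class ConsensusMapper:
    """Seed-and-extend mapper of consensus sequences against an assembly.

    Builds the genome k-mer index once; ``map`` then seeds with exact
    k_map-mers on both strands, clusters hits by genomic proximity, and
    verifies each cluster with an edlib infix alignment of the seeded
    consensus span against the candidate window.
    """

    def __init__(self, assembly: GenomeAssembly, params: MappingParams | None = None):
        self.assembly = assembly
        self.params = params or MappingParams()
        k = self.params.k_map
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in assembly.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((chrom, i))

    def map(self, consensus: str) -> list[tuple[GenomicInterval, float]]:
        p = self.params
        if len(consensus) < 2 * p.k_map:
            raise ValueError(f"consensus shorter than 2*k_map ({2 * p.k_map} bp)")
        hits: list[tuple[GenomicInterval, float]] = []
        for strand, query in (("+", consensus), ("-", revcomp(consensus))):
            hits.extend(self._map_strand(query, strand, len(consensus)))
        return _merge_hits(hits)

    def _map_strand(self, query: str, strand: str, full_len: int):
        p = self.params
        k = p.k_map
        # seeds per chrom as (diagonal, genome_pos, query_offset); clustering
        # by diagonal keeps adjacent copies of the same family apart (their
        # diagonals differ by about one copy length)
        seeds: dict[str, list[tuple[int, int, int]]] = {}
        for off in range(0, len(query) - k + 1):
            for chrom, gpos in self.index.get(query[off:off + k], ()):
                seeds.setdefault(chrom, []).append((gpos - off, gpos, off))
        band = max(20, int(0.15 * full_len))
        out = []
        for chrom, triples in seeds.items():
            triples.sort()
            cluster: list[tuple[int, int]] = []
            prev_diag = None
            for diag, gpos, off in triples + [(10 ** 15, 0, 0)]:
                if cluster and prev_diag is not None and diag - prev_diag > band:
                    hit = self._verify(chrom, strand, query, cluster, full_len)
                    if hit is not None:
                        out.append(hit)
                    cluster = []
                cluster.append((gpos, off))
                prev_diag = diag
            # (sentinel flushes the last cluster)
        return out

    def _verify(self, chrom, strand, query, cluster, full_len):
        p = self.params
        k = p.k_map
        seq = self.assembly.sequences[chrom]
        g_lo = min(g for g, _ in cluster)
        g_hi = max(g for g, _ in cluster) + k
        q_lo = min(o for _, o in cluster)
        q_hi = max(o for _, o in cluster) + k
        pad = max(30, (q_hi - q_lo) // 5)
        sub = query[max(0, q_lo - pad): min(len(query), q_hi + pad)]
        if len(sub) < p.min_length_fraction * full_len:
            return None
        w_lo = max(0, g_lo - (q_lo + pad) - 20)
        w_hi = min(len(seq), g_hi + (len(query) - q_hi) + pad + 20)
        window = seq[w_lo:w_hi]
        res = edlib.align(sub, window, mode="HW", task="locations")
        if res["editDistance"] < 0 or not res["locations"]:
            return None
        dist = res["editDistance"]
        loc = res["locations"][0]
        identity = 1.0 - dist / len(sub)
        if identity < p.min_identity:
            return None
        start, end = w_lo + loc[0], w_lo + loc[1] + 1
        if end - start < p.min_length_fraction * full_len:
            return None
        return GenomicInterval(chrom, start, end, strand), identity


def _merge_hits(hits):
    """Merge overlapping hits (either strand), keeping the best identity."""
    out = []
    for iv, ident in sorted(hits, key=lambda t: (t[0].chrom, t[0].start, -t[1])):
        if out and out[-1][0].overlap(iv) > 0.5 * min(len(out[-1][0]), len(iv)):
            if ident > out[-1][1]:
                out[-1] = (iv, ident)
            continue
        out.append((iv, ident))
    return out


def map_consensus(assembly: GenomeAssembly, consensus: str,
                  params: MappingParams | None = None) -> list[tuple[GenomicInterval, float]]:
    """One-shot convenience wrapper around :class:`ConsensusMapper`."""
    return ConsensusMapper(assembly, params).map(consensus)


# ---------------------------------------------------------------------------
# Locality classification


def classify_locality(family_id: str, instances: list[tuple[GenomicInterval, float]],
                      loci: list[GeneAnnotation],
                      params: LocalityParams | None = None) -> LocalityCall:
    """Classify one family LOCAL vs DISPERSED from its mapped instances."""
    params = params or LocalityParams()
    if len(instances) < 2:
        raise ValueError(f"{family_id}: need >= 2 instances to classify")
    if not loci:
        log.warning("%s: no loci supplied; calling DISPERSED", family_id)
        return LocalityCall(family_id, "DISPERSED", None, 0.0, len(instances))

    trees: dict[str, IntervalTree] = {}
    for g in loci:
        iv = g.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            max(0, iv.start - params.flank), iv.end + params.flank, g.gene_id)

    per_gene: dict[str, list[GenomicInterval]] = {}
    assignment: list[str | None] = []
    for iv, _ in instances:
        best_gene, best_ov = None, 0
        for hit in trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end):
            ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if ov >= params.inside_fraction * len(iv) and ov > best_ov:
                best_gene, best_ov = hit.data, ov
        assignment.append(best_gene)
        if best_gene is not None:
            per_gene.setdefault(best_gene, []).append(iv)

    if not per_gene:
        return LocalityCall(family_id, "DISPERSED", None, 0.0, len(instances))
    host = max(per_gene, key=lambda g: (len(per_gene[g]), g))
    frac = len(per_gene[host]) / len(instances)
    is_local = frac >= params.locality_min
    outside = [iv for (iv, _), g in zip(instances, assignment) if g != host]
    inside_lens = [len(iv) for iv in per_gene[host]]
    median_len = float(np.median(inside_lens)) if inside_lens else 0.0
    flags = []
    for i, iv in enumerate(outside):
        dists = [abs(iv.start - o.start) for j, o in enumerate(outside)
                 if j != i and o.chrom == iv.chrom]
        nearest = min(dists) if dists else None
        flags.append(OutsideFlags(iv, len(iv) < median_len, nearest))
    return LocalityCall(family_id, "LOCAL" if is_local else "DISPERSED",
                        host if is_local else None, frac, len(instances), flags)


# ---------------------------------------------------------------------------
# Per-gene burden


def compute_burden(lr_calls: list[LocalityCall],
                   lr_instances: dict[str, list[tuple[GenomicInterval, float]]],
                   tr_arrays: list, genes: list[GeneAnnotation],
                   assembly: GenomeAssembly | None = None,
                   count_families: bool = False) -> pd.DataFrame:
    """Length-normalized LR/TR burden per gene.

    ``n_lr`` counts instances of LOCAL families inside each gene (instances,
    not families, unless ``count_families``); ``n_tr`` counts tandem arrays
    overlapping the gene. Per-kb values divide by the gene span length.
    LR length and GC summaries are computed from the in-gene instances.
    """
    rows = []
    local = {c.family_id for c in lr_calls if c.call == "LOCAL"}
    for g in genes:
        span = g.interval
        if len(span) == 0:
            raise ValueError(f"zero-length gene {g.gene_id}")
        n_lr = 0
        lengths: list[int] = []
        gcs: list[float] = []
        for fam_id in local:
            inside = [iv for iv, _ in lr_instances.get(fam_id, [])
                      if iv.chrom == span.chrom
                      and span.overlap(iv) >= 0.5 * len(iv)]
            if not inside:
                continue
            n_lr += 1 if count_families else len(inside)
            for iv in inside:
                lengths.append(len(iv))
                if assembly is not None:
                    s = assembly.fetch(iv.chrom, iv.start, iv.end)
                    gcs.append((s.count("G") + s.count("C")) / len(s))
        n_tr = sum(1 for a in tr_arrays
                   if a.interval.chrom == span.chrom and span.overlap(a.interval) > 0)
        kb = len(span) / 1000
        rows.append(dict(gene_id=g.gene_id, biotype=g.biotype, length=len(span),
                         n_lr=n_lr, n_tr=n_tr,
                         lr_per_kb=n_lr / kb, tr_per_kb=n_tr / kb,
                         lr_mean_length=float(np.mean(lengths)) if lengths else 0.0,
                         lr_median_length=float(np.median(lengths)) if lengths else 0.0,
                         lr_mean_gc=float(np.mean(gcs)) if gcs else float("nan")))
    return pd.DataFrame(rows)
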
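"""Tandem-repeat detection by lag correlation, and routing of discovered
families into tandem (TR) vs local-repeat (LR) candidate catalogues.

The detector compares the sequence with itself at every lag p in
[1, max_period]: positions where s[i] == s[i+p] are self-matches, and maximal
runs whose windowed self-match fraction reaches ``purity_min`` (window = one
period) with total length >= 2p are reported as arrays. Overlapping calls at
different periods are resolved in favour of the smallest period whose purity
is within 0.05 of the best, which collapses the harmonics (a period-6 array
also matches at lag 12).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import seq_to_u8, u8_to_seq, BASE_CODES
from .formats_io import GenomicInterval
from .discovery import RepeatFamily


@dataclass
class TandemArray:
    interval: GenomicInterval
    period: int
    copy_number: float
    motif: str
    purity: float

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if len(self.interval) < 2 * self.period:
            raise ValueError("array shorter than two periods")


@dataclass
class TandemParams:
    min_period: int = 1
    max_period: int = 2000
    purity_min: float = 0.8
    min_matched_run: int = 6  # lag-matched positions; effective floor is max(2p, this)


def detect_tandem_arrays(sequence: str, params: TandemParams | None = None,
                         chrom: str = "chr1") -> list[TandemArray]:
    """Call tandem arrays in one sequence. Returns an empty list when nothing
    qualifies.

    Per period, runs of lag-matched windows are bridged across short impure
    gaps (<= 25% of the combined span) when the merged purity still clears
    ``purity_min``; a call needs at least max(2p, min_matched_run) matched
    positions, which keeps chance mono/di-nucleotide matches from flooding
    the output.
    """
    params = params or TandemParams()
    L = len(sequence)
    if params.max_period > L / 2:
        params = TandemParams(params.min_period, max(1, L // 2), params.purity_min,
                              params.min_matched_run)
    arr = seq_to_u8(sequence)
    calls: list[TandemArray] = []
    for p in range(params.min_period, params.max_period + 1):
        if 2 * p > L:
            break
        m = (arr[p:] == arr[:-p]).astype(np.int32)  # m[i]: s[i] vs s[i+p]
        if m.size < p:
            continue
        # windowed self-match fraction over one period
        cum = np.concatenate([[0], np.cumsum(m)])
        nwin = m.size - p + 1
        if nwin <= 0:
            continue
        frac = (cum[p:] - cum[:-p]) / p
        ok = frac >= params.purity_min
        if not ok.any():
            continue
        # a lag-match position qualifies when ANY window covering it passes;
        # this dilation keeps the detector symmetric under sequence reversal
        okc = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
        idx = np.arange(m.size)
        hi = np.minimum(idx, nwin - 1) + 1
        lo = np.maximum(idx - p + 1, 0)
        covered = (okc[hi] - okc[lo]) > 0
        edges = np.flatnonzero(np.diff(np.concatenate([[0], covered.view(np.int8), [0]])))
        runs = [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])]
        need = max(2 * p, params.min_matched_run)
        for a, b in _bridge_runs(runs, cum, params.purity_min, gap_max=2 * p):
            n_match = int(cum[b] - cum[a])
            if n_match < need:
                continue
            start, end = a, b + p  # covered sequence span
            purity = n_match / (b - a)
            motif = _frame_consensus(arr[start:end], p)
            calls.append(TandemArray(GenomicInterval(chrom, start, end), p,
                                     (end - start) / p, motif, purity))
    return _resolve_overlaps(calls)


def _bridge_runs(runs: list[tuple[int, int]], cum: np.ndarray, purity_min: float,
                 gap_max: int) -> list[tuple[int, int]]:
    """Close gaps <= gap_max between same-period runs (an order-independent
    closure, so the detector mirrors under sequence reversal); a closed group
    whose merged purity falls below purity_min falls back to its pieces."""
    if not runs:
        return runs
    groups: list[list[tuple[int, int]]] = [[runs[0]]]
    for a, b in runs[1:]:
        if a - groups[-1][-1][1] <= gap_max:
            groups[-1].append((a, b))
        else:
            groups.append([(a, b)])
    out = []
    for g in groups:
        a, b = g[0][0], g[-1][1]
        if len(g) == 1 or (cum[b] - cum[a]) / (b - a) >= purity_min:
            out.append((a, b))
        else:
            out.extend(g)
    return out


def _frame_consensus(arr: np.ndarray, period: int) -> str:
    """Majority base per position over the full period frames."""
    nf = arr.size // period
    frames = arr[: nf * period].reshape(nf, period)
    out = np.empty(period, dtype=np.uint8)
    for j in range(period):
        cnt = np.bincount(frames[:, j], minlength=256)[BASE_CODES]
        out[j] = BASE_CODES[int(np.argmax(cnt))]
    return u8_to_seq(out)


def _resolve_overlaps(calls: list[TandemArray]) -> list[TandemArray]:
    """Within each cluster of mutually overlapping calls keep the smallest
    period whose purity is within 0.05 of the cluster's best."""
    if not calls:
        return []
    calls = sorted(calls, key=lambda c: (c.interval.start, c.interval.end))
    clusters: list[list[TandemArray]] = [[calls[0]]]
    cur_end = calls[0].interval.end
    for c in calls[1:]:
        if c.interval.start < cur_end:
            clusters[-1].append(c)
            cur_end = max(cur_end, c.interval.end)
        else:
            clusters.append([c])
            cur_end = c.interval.end
    out = []
    for cl in clusters:
        best = max(c.purity for c in cl)
        eligible = [c for c in cl if c.purity >= best - 0.05]
        winner = min(eligible, key=lambda c: (c.period, -len(c.interval)))
        out.append(winner)
    return sorted(out, key=lambda c: c.interval.start)


# ---------------------------------------------------------------------------
# Routing


@dataclass
class SplitParams:
    tandem_overlap: float = 0.5  # fraction of instance bp inside arrays
    gap_max: int = 10  # bp; adjacency threshold between consecutive instances
    adjacent_frac: float = 0.5  # fraction of consecutive pairs that are adjacent


def split_tandem(families: list[RepeatFamily], arrays: list[TandemArray],
                 params: SplitParams | None = None
                 ) -> tuple[list[RepeatFamily], list[RepeatFamily]]:
    """Partition discovered families into (tr_catalog, lr_candidates).

    A family is tandem if >= ``tandem_overlap`` of its instance base pairs lie
    inside detected tandem arrays, or if its own instances are adjacent
    (gap <= ``gap_max``) in >= ``adjacent_frac`` of consecutive pairs. Every
    input family lands in exactly one catalogue.
    """
    params = params or SplitParams()
    merged = _merge_by_chrom([a.interval for a in arrays])
    tr, lr = [], []
    for fam in families:
        total_bp = sum(len(iv) for iv, _ in fam.instances)
        in_arrays = sum(_covered(iv, merged.get(iv.chrom, [])) for iv, _ in fam.instances)
        frac = in_arrays / total_bp if total_bp else 0.0
        ivs = sorted((iv for iv, _ in fam.instances), key=lambda v: (v.chrom, v.start))
        pairs = [(a, b) for a, b in zip(ivs, ivs[1:]) if a.chrom == b.chrom]
        adj = sum(1 for a, b in pairs if b.start - a.end <= params.gap_max)
        adjacent = bool(pairs) and adj / len(pairs) >= params.adjacent_frac
        (tr if frac >= params.tandem_overlap or adjacent else lr).append(fam)
    return tr, lr


def _merge_by_chrom(intervals: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
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


def _covered(iv: GenomicInterval, spans: list[tuple[int, int]]) -> int:
    return sum(max(0, min(iv.end, e) - max(iv.start, s)) for s, e in spans)
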
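"""PSSM motif scanning with exact match p-values.

A position frequency matrix is turned into log2-odds scores with a
pseudocount of 0.8 per cell over the background. Both strands of every
sequence are scanned; a window's match p-value is the probability, under the
i.i.d. background model, of a score at least as high — computed exactly by
dynamic programming over the per-column score distribution (for the widths
handled exactly, the partial sums are accumulated left-to-right, so the DP
reproduces brute-force word enumeration bit for bit). Hits at p <= cutoff
(default 1e-6) are reported with Benjamini-Hochberg q-values over all windows
tested per motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seq import revcomp, seq_to_u8, BASE_CODES
from .formats_io import PFMatrix, GenomicInterval

log = logging.getLogger(__name__)

EXACT_WIDTH_LIMIT = 12  # dict-DP is exact; above this, scores are quantized
QUANT = 1e-4  # score grid for wide motifs


@dataclass
class MotifHit:
    motif_id: str
    sequence_id: str
    interval: GenomicInterval
    strand: str
    score: float
    p_value: float
    q_value: float = float("nan")


def log_odds(pfm: PFMatrix, pseudocount: float = 0.8) -> np.ndarray:
    """4 x W log2-odds matrix with the pseudocount applied per cell."""
    counts = pfm.counts + pseudocount
    probs = counts / counts.sum(axis=0, keepdims=True)
    return np.log2(probs / pfm.background[:, None])


def score_distribution(lom: np.ndarray, background: np.ndarray) -> dict[float, float]:
    """Exact distribution of window scores under the i.i.d. background.

    Dict mapping score -> probability. For widths above EXACT_WIDTH_LIMIT the
    per-column scores are quantized to a QUANT grid to bound the state count.
    """
    W = lom.shape[1]
    exact = W <= EXACT_WIDTH_LIMIT
    dist: dict[float, float] = {0.0: 1.0}
    for j in range(W):
        new: dict[float, float] = {}
        for s, p in dist.items():
            for b in range(4):
                val = s + lom[b, j]
                if not exact:
                    val = round(val / QUANT) * QUANT
                new[val] = new.get(val, 0.0) + p * background[b]
        dist = new
    return dist


def match_pvalue(dist: dict[float, float], score: float, tol: float = 0.0) -> float:
    """P(window score >= observed) under the background."""
    return float(sum(p for s, p in dist.items() if s >= score - tol))


def scan_motifs(pfms: list[PFMatrix], sequences: dict[str, str],
                cutoff: float = 1e-6, pseudocount: float = 0.8) -> list[MotifHit]:
    """Scan sequences with each motif on both strands; report hits with exact
    match p-value <= cutoff, BH-corrected per motif over all windows tested."""
    hits: list[MotifHit] = []
    for pfm in pfms:
        W = pfm.width
        usable = {sid: s for sid, s in sequences.items() if len(s) >= W}
        if not usable:
            log.warning("motif %s wider than every sequence; skipping", pfm.motif_id)
            continue
        lom = log_odds(pfm, pseudocount)
        dist = score_distribution(lom, pfm.background)
        # map score -> p once: sorted tail sums
        s_sorted = np.array(sorted(dist))
        p_sorted = np.array([dist[s] for s in s_sorted])
        tail = np.cumsum(p_sorted[::-1])[::-1]

        def pval(score: float) -> float:
            i = np.searchsorted(s_sorted, score - 1e-12)
            return float(tail[i]) if i < tail.size else 0.0

        motif_hits: list[MotifHit] = []
        n_tested = 0
        for sid, seq in usable.items():
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                scores = _window_scores(s, lom)
                n_tested += scores.size
                for off in np.nonzero(scores > -np.inf)[0]:
                    p = pval(float(scores[off]))
                    if p <= cutoff:
                        if strand == "+":
                            start = int(off)
                        else:
                            start = len(seq) - int(off) - W
                        motif_hits.append(MotifHit(
                            pfm.motif_id, sid,
                            GenomicInterval(sid, start, start + W, strand),
                            strand, float(scores[off]), p))
        _bh_correct(motif_hits, n_tested)
        hits.extend(motif_hits)
    return hits


def _window_scores(seq: str, lom: np.ndarray) -> np.ndarray:
    """Score of every window; -inf where the window contains a non-ACGT base."""
    W = lom.shape[1]
    arr = seq_to_u8(seq)
    if arr.size < W:
        return np.array([])
    code = np.full(256, -1, dtype=np.int64)
    code[BASE_CODES] = np.arange(4)
    idx = code[arr]
    n_win = arr.size - W + 1
    out = np.zeros(n_win)
    ok = np.ones(n_win, dtype=bool)
    for j in range(W):
        col = idx[j:j + n_win]
        valid = col >= 0
        ok &= valid
        out += np.where(valid, lom[np.clip(col, 0, 3), j], 0.0)
    out[~ok] = -np.inf
    return out


def _bh_correct(hits: list[MotifHit], n_tested: int) -> None:
    """Benjamini-Hochberg q-values with m = all windows tested for the motif.

    Unreported windows necessarily have larger p-values than any reported
    hit, so the hits' ranks among all tests equal their ranks among hits.
    """
    if not hits:
        return
    order = sorted(range(len(hits)), key=lambda i: hits[i].p_value)
    q_prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = len(order) - rank_from_end
        q = min(q_prev, hits[i].p_value * n_tested / rank)
        hits[i].q_value = q
        q_prev = q
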
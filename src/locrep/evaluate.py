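"""Scoring of pipeline output against a simulation's planted ground truth.

Matches discovered families to planted consensi (strand-aware edlib
identity), measures instance recall against the truth table, and quantifies
how much planted tandem material ended up in the TR catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import pandas as pd

from ._seq import revcomp
from .discovery import RepeatFamily
from .locality import LocalityCall
from .synthetic import TruthTable


def consensus_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned as an infix of the longer,
    on the better strand: 1 - dist/len(shorter)."""
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    best = min(edlib.align(query, target, mode="HW", task="distance")["editDistance"],
               edlib.align(revcomp(query), target, mode="HW", task="distance")["editDistance"])
    return max(0.0, 1.0 - best / len(query))


@dataclass
class FamilyMatch:
    planted_id: str
    discovered_id: str | None
    identity: float  # consensus identity to the planted consensus
    instance_recall: float  # planted instances overlapped by discovered ones


def match_families(discovered: list[RepeatFamily], truth: TruthTable,
                   min_overlap: float = 0.5) -> list[FamilyMatch]:
    """Best discovered family per planted family, by instance overlap."""
    out = []
    for fam_id, cons in truth.consensi.items():
        planted = truth.family_instances(fam_id)
        best, best_recall = None, -1.0
        for fam in discovered:
            hit = 0
            for row in planted.itertuples():
                for iv, _ in fam.instances:
                    ov = max(0, min(iv.end, row.end) - max(iv.start, row.start))
                    if iv.chrom == row.chrom and ov >= min_overlap * (row.end - row.start):
                        hit += 1
                        break
            recall = hit / len(planted) if len(planted) else 0.0
            if recall > best_recall:
                best, best_recall = fam, recall
        if best is None or best_recall == 0.0:
            out.append(FamilyMatch(fam_id, None, 0.0, 0.0))
        else:
            # identity measured over the region the discovered consensus covers
            ident = consensus_identity(best.consensus, cons)
            out.append(FamilyMatch(fam_id, best.family_id, ident, best_recall))
    return out


def locality_accuracy(matches: list[FamilyMatch], calls: list[LocalityCall],
                      truth: TruthTable) -> dict:
    """Fractions of planted-local families called LOCAL (with consensus
    identity >= 0.9) and of planted-dispersed families wrongly called LOCAL."""
    call_by_id = {c.family_id: c for c in calls}
    local_ids = sorted({r.family_id for r in truth.instances.itertuples() if r.host})
    disp_ids = sorted({r.family_id for r in truth.instances.itertuples() if not r.host})
    n_local_ok = 0
    for m in matches:
        if m.planted_id not in local_ids:
            continue
        c = call_by_id.get(m.discovered_id)
        if c is not None and c.call == "LOCAL" and m.identity >= 0.9:
            n_local_ok += 1
    n_disp_bad = 0
    for m in matches:
        if m.planted_id not in disp_ids:
            continue
        c = call_by_id.get(m.discovered_id)
        if c is not None and c.call == "LOCAL":
            n_disp_bad += 1
    return dict(
        n_planted_local=len(local_ids),
        n_recovered_local=n_local_ok,
        local_recovery=n_local_ok / len(local_ids) if local_ids else float("nan"),
        n_planted_dispersed=len(disp_ids),
        n_false_local=n_disp_bad,
    )


def tandem_routing_fraction(tr_catalog: list[RepeatFamily],
                            lr_candidates: list[RepeatFamily],
                            truth: TruthTable) -> float:
    """Of the discovered-instance base pairs lying inside planted tandem
    arrays, the fraction routed to the TR catalogue (1.0 when no discovered
    family touches planted tandem material)."""
    spans = [(r.chrom, r.start, r.end) for r in truth.tandem_arrays.itertuples()]

    def tandem_bp(fams: list[RepeatFamily]) -> int:
        total = 0
        for fam in fams:
            for iv, _ in fam.instances:
                total += sum(max(0, min(iv.end, e) - max(iv.start, s))
                             for c, s, e in spans if c == iv.chrom)
        return total

    in_tr = tandem_bp(tr_catalog)
    in_lr = tandem_bp(lr_candidates)
    if in_tr + in_lr == 0:
        return 1.0
    return in_tr / (in_tr + in_lr)


def instance_recall_table(matches: list[FamilyMatch]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in matches])
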
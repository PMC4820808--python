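"""Readers and writers for the standard formats the pipeline touches.

Conventions fixed here once and for all:

* internal coordinates are 0-based half-open on every interval type; GTF's
  1-based closed coordinates are converted at the I/O boundary only;
* sequences are uppercase over {A,C,G,T,N} (U folded to T, anything else
  replaced by N with a warning);
* all writers end files with a newline; BED output is tab-separated with no
  header.

Newick serialization lives with the tree type in :mod:`locrep.phylo` and is
re-exported here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
_BIOTYPES = {"lncRNA", "mRNA", "other"}


@dataclass
class GenomeAssembly:
    """A set of named nucleotide sequences (uppercase A/C/G/T/N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("assembly has no sequences")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"sequence {name!r} has invalid characters {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneAnnotation:
    gene_id: str
    interval: GenomicInterval
    biotype: str = "other"
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in _BIOTYPES:
            raise ValueError(f"biotype {self.biotype!r} not in {sorted(_BIOTYPES)}")
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene {self.gene_id}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class PFMatrix:
    """Position frequency matrix, rows ordered A, C, G, T."""

    motif_id: str
    counts: np.ndarray  # shape (4, W)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: counts must be 4 x W with W >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"motif {self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly`.

    Sequences are uppercased, U folded to T; any other non-ACGTN character is
    replaced by N with a logged warning. Duplicate headers are an error.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        cleaned = re.sub("[^ACGTN]", "N", seq)
        n_repl = sum(a != b for a, b in zip(seq, cleaned))
        if n_repl:
            log.warning("%s: %d non-ACGTN characters replaced by N in %s", path, n_repl, rec.id)
        sequences[rec.id] = cleaned
    if not sequences:
        raise ValueError(f"no sequences in FASTA file {path}")
    return GenomeAssembly(sequences)


def write_fasta(path: str | Path, sequences: dict[str, str] | GenomeAssembly, width: int = 70) -> None:
    if isinstance(sequences, GenomeAssembly):
        sequences = sequences.sequences
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# BED / GTF


def read_intervals(path: str | Path, dialect: str = "BED") -> list:
    """Read genomic intervals (BED) or gene annotations (GTF).

    BED coordinates pass through unchanged (they are already the internal
    convention); GTF 1-based closed coordinates are converted to 0-based
    half-open. Strand defaults to '.' when absent.
    """
    dialect = dialect.upper()
    if dialect == "BED":
        return _read_bed(path)
    if dialect == "GTF":
        return _read_gtf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with < 3 fields")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            out.append(GenomicInterval(f[0], start, end, strand, name))
    return out


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _read_gtf(path: str | Path) -> list[GeneAnnotation]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: GTF line with < 9 fields")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = f[:9]
            start, end = int(start1) - 1, int(end1)  # 1-based closed -> 0-based half-open
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end after conversion")
            attr = dict(_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id", "")
            if not gid:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            strand = strand if strand in "+-" else "."
            iv = GenomicInterval(chrom, start, end, strand, gid)
            if gid not in genes:
                genes[gid] = {"interval": None, "exons": [], "biotype": "other"}
                order.append(gid)
            if feature == "gene":
                genes[gid]["interval"] = iv
                genes[gid]["biotype"] = _map_biotype(attr.get("gene_biotype", attr.get("gene_type", "")))
            elif feature == "exon":
                genes[gid]["exons"].append(iv)
    out = []
    for gid in order:
        g = genes[gid]
        iv = g["interval"]
        if iv is None:  # gene span from exons if no explicit gene feature
            exs = g["exons"]
            iv = GenomicInterval(exs[0].chrom, min(e.start for e in exs), max(e.end for e in exs), exs[0].strand, gid)
        out.append(GeneAnnotation(gid, iv, g["biotype"], g["exons"]))
    return out


def _map_biotype(raw: str) -> str:
    if raw in ("protein_coding", "mRNA"):
        return "mRNA"
    if raw in ("lncRNA", "lincRNA", "antisense", "processed_transcript"):
        return "lncRNA"
    return "other"


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval], scores: Sequence[float] | None = None) -> None:
    """Write intervals as BED6 (tab-separated, no header, trailing newline)."""
    intervals = list(intervals)
    if scores is None:
        scores = [0] * len(intervals)
    with open(path, "w") as fh:
        for iv, sc in zip(intervals, scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{int(round(sc))}\t{iv.strand}\n")


def write_gtf(path: str | Path, genes: Iterable[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            bt = {"mRNA": "protein_coding"}.get(g.biotype, g.biotype)
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{bt}";'
            fh.write(f"{iv.chrom}\tlocrep\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n")
            for ex in g.exons:
                fh.write(f"{ex.chrom}\tlocrep\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# JASPAR plain-text PFM


def read_pfm(path: str | Path) -> list[PFMatrix]:
    """Read JASPAR plain-text PFMs (4 labelled rows per motif)."""
    motifs: list[PFMatrix] = []
    motif_id = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines.append(">")  # sentinel to flush the last motif

    def flush() -> None:
        if motif_id is None:
            return
        if set(rows) != set("ACGT"):
            raise ValueError(f"motif {motif_id}: expected rows A,C,G,T, got {sorted(rows)}")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise ValueError(f"motif {motif_id}: rows of unequal width {sorted(widths)}")
        motifs.append(PFMatrix(motif_id, np.array([rows[b] for b in "ACGT"])))

    for line in lines:
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            motif_id = line[1:].split()[0] if line[1:].strip() else None
            rows = {}
        else:
            m = re.match(r"\s*([ACGTacgt])\s*[:|]?\s*\[?([^\]]*)\]?", line)
            if not m:
                raise ValueError(f"unparseable PFM row: {line!r}")
            rows[m.group(1).upper()] = [float(x) for x in m.group(2).split()]
    return motifs


def write_pfm(path: str | Path, motifs: Iterable[PFMatrix]) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id}\n")
            for i, base in enumerate("ACGT"):
                vals = " ".join(f"{v:g}" for v in m.counts[i])
                fh.write(f"{base} [ {vals} ]\n")


def merged_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the union of the intervals."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


# newick serialization lives with the tree type; re-exported here as part of
# the formats surface
from .phylo import parse_newick, write_newick  # noqa: E402,F401
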
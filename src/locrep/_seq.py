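"""Low-level nucleotide helpers shared across modules.

Sequences are plain uppercase strings over {A,C,G,T,N}; hot loops convert to
numpy uint8 arrays of ASCII codes.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

# ASCII codes for the four bases, used by array-level code
A, C, G, T, N = (ord(b) for b in "ACGTN")
BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_x] = _y


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def u8_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_u8(arr: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[arr][::-1]


def canonical_kmer(kmer: str) -> tuple[str, str]:
    """Return (canonical form, strand) where the canonical form is the
    lexicographically smaller of the k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return (kmer, "+") if kmer <= rc else (rc, "-")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. background sequence at the requested GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return u8_to_seq(rng.choice(BASE_CODES, size=length, p=p))
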
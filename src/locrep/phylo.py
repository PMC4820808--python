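"""Multiple alignment, distance matrices, neighbor-joining, and bootstrap
supports for repeat ortholog sets.

The built-in progressive aligner (global DP, match +1 / mismatch -1 /
gap open -4 / gap extend -1, guide order by single-linkage clustering on
shared 8-mer distance) replaces an external MSA tool; externally computed
aligned FASTA can be ingested verbatim instead. Distances are Jukes-Cantor
on gap-excluded columns by default (p-distance available; JC saturation at
p >= 0.75 maps to a finite ceiling of 10 substitutions/site). Trees are
built by Saitou-Nei neighbor joining — iteratively joining the pair
minimizing Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k) — with
negative branch lengths clamped to zero and the deficit moved to the sister
branch. Bootstrap supports are the percentage of column-resampled replicate
trees containing each bipartition of the original tree; the consensus report
lists the bipartitions above 50%.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from ._seq import seq_to_u8, u8_to_seq

JC_CEILING = 10.0  # distance assigned at JC saturation (p >= 0.75)
_GAP = ord("-")
_NCODE = ord("N")


# ---------------------------------------------------------------------------
# Alignment container


@dataclass
class Alignment:
    labels: list[str]
    rows: list[str]  # equal-length, over {A,C,G,T,N,-}

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(widths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.stack([seq_to_u8(r) for r in self.rows])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        mat = self.matrix()[:, cols]
        return Alignment(list(self.labels), [u8_to_seq(row) for row in mat])


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    model: str = "jukes_cantor"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(self.d < 0):
            raise ValueError("negative distances")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")


# ---------------------------------------------------------------------------
# Progressive alignment


@dataclass
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


def _pair_score_matrix(p1: np.ndarray, p2: np.ndarray, params: AlignParams) -> np.ndarray:
    """Expected column score between two profiles (n1_cols x 4) and (n2_cols x 4)."""
    same = p1 @ p2.T
    return params.match * same + params.mismatch * (1.0 - same)


def _profile(mat: np.ndarray) -> np.ndarray:
    """Columns x 4 base frequencies (gaps and N excluded from the norm)."""
    out = np.zeros((mat.shape[1], 4))
    for k, b in enumerate(b"ACGT"):
        out[:, k] = (mat == b).sum(axis=0)
    norm = out.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return out / norm


def _align_profiles(m1: np.ndarray, m2: np.ndarray, params: AlignParams
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Global affine-gap DP between two alignment blocks; returns the two
    blocks expanded with gap columns. Tie-break prefers diagonal, then up."""
    n1, n2 = m1.shape[1], m2.shape[1]
    S = _pair_score_matrix(_profile(m1), _profile(m2), params)
    go, ge = params.gap_open, params.gap_extend
    NEG = -1e18
    M = np.full((n1 + 1, n2 + 1), NEG)
    X = np.full((n1 + 1, n2 + 1), NEG)  # gap in m2 (vertical, consumes m1)
    Y = np.full((n1 + 1, n2 + 1), NEG)  # gap in m1 (horizontal, consumes m2)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, n2 + 1):
        Y[0, j] = go + ge * (j - 1)
    for i in range(1, n1 + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        base = np.maximum(prevM, prevY)
        X[i, 1:] = np.maximum(base[1:] + go, prevX[1:] + ge)
        X[i, 0] = max(base[0] + go, prevX[0] + ge)
        diag = np.maximum(np.maximum(prevM[:-1], prevX[:-1]), prevY[:-1]) + S[i - 1]
        M[i, 1:] = diag
        # Y has a within-row dependency; resolve with a running max:
        # Y[i,j] = max over k<j of (best[i,k] + go + ge*(j-1-k))
        best = np.maximum(M[i], X[i])
        run = NEG
        for j in range(1, n2 + 1):
            run = max(run + ge, best[j - 1] + go)
            Y[i, j] = run
            best[j] = max(best[j], Y[i, j])
    # traceback; preference order at ties: diagonal (M), then up (X), then left (Y)
    def close(a: float, b: float) -> bool:
        return abs(a - b) < 1e-9

    i, j = n1, n2
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    out1, out2 = [], []
    gap1 = np.full((m1.shape[0], 1), _GAP, dtype=np.uint8)
    gap2 = np.full((m2.shape[0], 1), _GAP, dtype=np.uint8)
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out1.append(m1[:, i - 1:i]); out2.append(m2[:, j - 1:j])
            target = M[i, j] - S[i - 1, j - 1]
            for st, val in ((0, M[i - 1, j - 1]), (1, X[i - 1, j - 1]), (2, Y[i - 1, j - 1])):
                if close(val, target):
                    state = st
                    break
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            out1.append(m1[:, i - 1:i]); out2.append(gap2)
            if close(X[i, j], X[i - 1, j] + ge):
                state = 1
            elif close(X[i, j], M[i - 1, j] + go):
                state = 0
            else:
                state = 2
            i -= 1
        elif state == 2 and j > 0:
            out1.append(gap1); out2.append(m2[:, j - 1:j])
            if close(Y[i, j], M[i, j - 1] + go):
                state = 0
            elif close(Y[i, j], X[i, j - 1] + go):
                state = 1
            else:
                state = 2
            j -= 1
        elif i > 0:
            out1.append(m1[:, i - 1:i]); out2.append(gap2); i -= 1; state = 1
        else:
            out1.append(gap1); out2.append(m2[:, j - 1:j]); j -= 1; state = 2
    a1 = np.concatenate(out1[::-1], axis=1) if out1 else m1[:, :0]
    a2 = np.concatenate(out2[::-1], axis=1) if out2 else m2[:, :0]
    return a1, a2


def pairwise_align_score(s1: str, s2: str, params: AlignParams | None = None) -> float:
    """Optimal global alignment score of two sequences (affine gaps)."""
    params = params or AlignParams()
    m1 = seq_to_u8(s1)[None, :]
    m2 = seq_to_u8(s2)[None, :]
    a1, a2 = _align_profiles(m1, m2, params)
    return _alignment_score(a1[0], a2[0], params)


def _alignment_score(r1: np.ndarray, r2: np.ndarray, params: AlignParams) -> float:
    score = 0.0
    in_gap = 0  # 0 none, 1 gap in r2, 2 gap in r1
    for a, b in zip(r1, r2):
        if a == _GAP:
            score += params.gap_extend if in_gap == 2 else params.gap_open
            in_gap = 2
        elif b == _GAP:
            score += params.gap_extend if in_gap == 1 else params.gap_open
            in_gap = 1
        else:
            score += params.match if a == b else params.mismatch
            in_gap = 0
    return score


def _kmer_set(seq: str, k: int = 8) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def progressive_align(sequences: dict[str, str],
                      params: AlignParams | None = None) -> Alignment:
    """Progressive MSA: guide order from single-linkage clustering on shared
    8-mer distance, blocks merged by global profile-profile DP."""
    params = params or AlignParams()
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    for label, s in sequences.items():
        if not s:
            raise ValueError(f"sequence {label!r} is empty")
    labels = sorted(sequences)
    n = len(labels)
    ksets = [_kmer_set(sequences[l]) for l in labels]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(ksets[i] & ksets[j])
            denom = min(len(ksets[i]), len(ksets[j])) or 1
            D[i, j] = D[j, i] = 1.0 - inter / denom
    # single-linkage agglomeration gives the merge order
    clusters: dict[int, tuple[list[str], np.ndarray]] = {
        i: ([labels[i]], seq_to_u8(sequences[labels[i]])[None, :]) for i in range(n)}
    active = list(range(n))
    cd = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    nxt = n
    while len(active) > 1:
        (i, j) = min(((a, b) for a in active for b in active if a < b),
                     key=lambda ab: (cd[ab], ab))
        li, mi = clusters.pop(i)
        lj, mj = clusters.pop(j)
        ai, aj = _align_profiles(mi, mj, params)
        clusters[nxt] = (li + lj, np.concatenate([ai, aj], axis=0))
        active = [a for a in active if a not in (i, j)] + [nxt]
        for a in active[:-1]:
            key = (min(a, nxt), max(a, nxt))
            cd[key] = min(cd[(min(a, i), max(a, i))], cd[(min(a, j), max(a, j))])
        nxt += 1
    merged_labels, mat = clusters[active[0]]
    order = [merged_labels.index(l) for l in labels]
    return Alignment(labels, [u8_to_seq(mat[k]) for k in order])


# ---------------------------------------------------------------------------
# Identity and distances


def pairwise_identity(alignment: Alignment) -> np.ndarray:
    """identity(i,j) = matches / columns where neither row has a gap or N;
    NaN when no column is comparable."""
    mat = alignment.matrix()
    n = mat.shape[0]
    usable = (mat != _GAP) & (mat != _NCODE)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = usable[i] & usable[j]
            cnt = int(both.sum())
            if cnt == 0:
                out[i, j] = out[j, i] = float("nan")
            else:
                ident = float((mat[i, both] == mat[j, both]).mean())
                out[i, j] = out[j, i] = ident
    return out


def p_distance(alignment: Alignment) -> DistanceMatrix:
    ident = pairwise_identity(alignment)
    d = 1.0 - np.nan_to_num(ident, nan=0.25)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(alignment.labels), d, "p_distance")


def jukes_cantor(alignment: Alignment) -> DistanceMatrix:
    """JC69 distance -(3/4) ln(1 - 4p/3); saturation mapped to a ceiling."""
    pd = p_distance(alignment).d
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 1.0 - 4.0 * pd / 3.0
        d = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), JC_CEILING)
    d = np.minimum(d, JC_CEILING)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(list(alignment.labels), d, "jukes_cantor")


def distance_matrix(alignment: Alignment, model: str = "jukes_cantor") -> DistanceMatrix:
    if model == "jukes_cantor":
        return jukes_cantor(alignment)
    if model == "p_distance":
        return p_distance(alignment)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    label: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: int | None = None  # bootstrap %, internal branches only

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c._nwk(ws)}:{bl:.6g}" for c, bl in self.children)
        lab = str(self.support) if (ws and self.support is not None) else self.label
        return f"({inner}){lab}"


@dataclass
class PhyloTree:
    root: TreeNode  # rooted at the final NJ trifurcation; topology is unrooted
    labels: list[str]

    def newick(self, with_support: bool = True) -> str:
        return self.root.newick(with_support)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the leaf set not containing the
        first taxon (the canonical side)."""
        all_leaves = frozenset(self.labels)
        anchor = min(self.labels)
        out = set()

        def walk(node: TreeNode):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(self.labels) - 1:
                    canon = side if anchor not in side else all_leaves - side
                    out.add(canon)
                walk(child)

        walk(self.root)
        return out

    def _internal_edges(self) -> list[tuple[TreeNode, frozenset]]:
        all_leaves = frozenset(self.labels)
        anchor = min(self.labels)
        out = []

        def walk(node: TreeNode):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(self.labels) - 1:
                    canon = side if anchor not in side else all_leaves - side
                    out.append((child, canon))
                walk(child)

        walk(self.root)
        return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining. Ties in the Q criterion break by label
    order; negative branch lengths are clamped to 0 with the deficit moved to
    the sister branch."""
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    D = dm.d.copy()
    nodes = [TreeNode(l) for l in labels]
    sort_keys = list(labels)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best, best_q = None, math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, min(sort_keys[i], sort_keys[j]), max(sort_keys[i], sort_keys[j]))
                if best is None or key < best_q_key:
                    best, best_q_key = (i, j), key
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode("", [(nodes[i], li), (nodes[j], lj)])
        # distances to the new node
        newD = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            newD[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newD
        D[:-1, -1] = newD
        nodes.append(new)
        sort_keys.append(min(sort_keys[i], sort_keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # final trifurcation
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode("", [(nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0)),
                         (nodes[k], max(lk, 0.0))])
    return PhyloTree(root, sorted(labels))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += -li  # deficit moved to the sister branch
        li = 0.0
    if lj < 0:
        li += -lj
        lj = 0.0
    return li, lj


def bootstrap_support(alignment: Alignment, n_boot: int = 100, seed: int = 0,
                      model: str = "jukes_cantor") -> tuple[PhyloTree, dict[frozenset, int]]:
    """Column-resampling bootstrap: support of each internal branch of the
    original-data NJ tree = percentage of replicate trees containing the same
    bipartition. Replicate i draws from seed + i."""
    if len(alignment.labels) < 4:
        raise ValueError("need >= 4 taxa for bootstrap supports")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    tree = nj_tree(distance_matrix(alignment, model))
    counts: dict[frozenset, int] = {bp: 0 for _, bp in tree._internal_edges()}
    for i in range(n_boot):
        rng = np.random.default_rng(seed + i)
        rep = alignment.resample_columns(rng)
        rep_tree = nj_tree(distance_matrix(rep, model))
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: round(100 * c / n_boot) for bp, c in counts.items()}
    for node, bp in tree._internal_edges():
        node.support = supports[bp]
    return tree, supports


def consensus_report(supports: dict[frozenset, int], threshold: int = 50) -> list[tuple[frozenset, int]]:
    """Bipartitions with support above the threshold, best first."""
    return sorted(((bp, s) for bp, s in supports.items() if s > threshold),
                  key=lambda t: (-t[1], sorted(t[0])))


# ---------------------------------------------------------------------------
# Newick


def parse_newick(text: str) -> TreeNode:
    """Parse a newick string; internal labels (e.g. integer supports) are
    accepted and stored on the node."""
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                child, bl = parse_node()
                node.children.append((child, bl))
                if s[pos] == ",":
                    pos += 1
                elif s[pos] == ")":
                    pos += 1
                    break
        m = re.match(r"[^,():;]*", s[pos:])
        label = m.group(0)
        pos += len(label)
        if node.children and re.fullmatch(r"\d+", label):
            node.support = int(label)
        else:
            node.label = label
        bl = 0.0
        if pos < len(s) and s[pos] == ":":
            m = re.match(r":([-\d.eE+]+)", s[pos:])
            bl = float(m.group(1))
            pos += len(m.group(0))
        return node, bl

    node, _ = parse_node()
    return node


def write_newick(path: str, tree: PhyloTree, with_support: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick(with_support) + "\n")
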
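"""Multiple sequence alignment via progressive profile merging.

A deliberately compact progressive aligner: k-mer count distances feed a
UPGMA guide tree, and profiles are merged bottom-up with a global
affine-gap Needleman-Wunsch over expected BLOSUM62 column scores.  Gap
costs follow the ``open + (L-1)*extend`` convention for a gap of length
L.  Pre-aligned (gapped) FASTA can be loaded directly to skip this stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from cmcpminer.seq_io import SequenceRecord

GAP = "-"
AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
#: BLOSUM62 as a dense 20x20 array in AA order
BLOSUM62 = np.array([[float(_BLOSUM62[a][b]) for b in AA] for a in AA])

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass
class Alignment:
    """A gapped multiple alignment of one family's member sequences."""

    family: str
    ids: list[str]
    rows: list[str]

    @property
    def ncol(self) -> int:
        return len(self.rows[0])

    @property
    def nrow(self) -> int:
        return len(self.rows)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return col.count(GAP) / len(col)


def _residue_score(a: str, b: str) -> float:
    """BLOSUM62 score; unknown residues (X etc.) score 0."""
    ia, ib = AA_INDEX.get(a), AA_INDEX.get(b)
    if ia is None or ib is None:
        return 0.0
    return BLOSUM62[ia, ib]


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies over non-gap symbols (ncol x 20)."""
    ncol = len(rows[0])
    freqs = np.zeros((ncol, 20))
    for r in rows:
        for j, c in enumerate(r):
            idx = AA_INDEX.get(c)
            if idx is not None:
                freqs[j, idx] += 1.0
    tot = freqs.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return freqs / tot


def _affine_global(
    S: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[list[tuple[int, int]], float]:
    """Global affine-gap DP over a column-score matrix S (n x m).

    Returns the traceback path as (i, j) moves where i/j of -1 denotes a
    gap in that dimension, and the optimal score.  Ties break diagonal,
    then up (gap in columns of S), then left.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in second profile (consume i)
    Y = np.full((n + 1, m + 1), NEG)  # gap in first profile (consume j)
    M[0, 0] = 0.0
    X[1:, 0] = -(gap_open + np.arange(n) * gap_extend)
    Y[0, 1:] = -(gap_open + np.arange(m) * gap_extend)
    # row-vectorised DP; the within-row Y scan uses a running-max identity:
    # Y[i,j] = max_{k<j} (A[k] - (j-1-k)*ge) with A = max(M, X) - open
    jm = np.arange(m)
    for i in range(1, n + 1):
        M[i, 1:] = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]),
                              Y[i - 1, :-1]) + S[i - 1, :]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - gap_open,
            X[i - 1, 1:] - gap_extend,
        )
        A = np.maximum(M[i, :-1], X[i, :-1]) - gap_open
        runmax = np.maximum.accumulate(A + jm * gap_extend)
        Y[i, 1:] = runmax - jm * gap_extend
    # traceback: prefer M (diagonal), then X (up), then Y (left)
    path: list[tuple[int, int]] = []
    i, j = n, m
    # deterministic: pick first of M, X, Y attaining the max
    best = max(M[i, j], X[i, j], Y[i, j])
    state = "M"
    for k, mat in (("M", M), ("X", X), ("Y", Y)):
        if mat[i, j] == best:
            state = k
            break
    score = best
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for k, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i, j] - prev) < 1e-9:
                    state = k
                    break
        elif state == "X":
            path.append((i - 1, -1))
            val = X[i, j]
            i = i - 1
            if abs(M[i, j] - gap_open - val) < 1e-9:
                state = "M"
            elif abs(X[i, j] - gap_extend - val) < 1e-9:
                state = "X"
            else:
                state = "Y"
        else:
            path.append((-1, j - 1))
            val = Y[i, j]
            j = j - 1
            if abs(M[i, j] - gap_open - val) < 1e-9:
                state = "M"
            elif abs(Y[i, j] - gap_extend - val) < 1e-9:
                state = "Y"
            else:
                state = "X"
        if i == 0 and j > 0:
            while j > 0:
                path.append((-1, j - 1))
                j -= 1
        elif j == 0 and i > 0:
            while i > 0:
                path.append((i - 1, -1))
                i -= 1
    path.reverse()
    return path, float(score)


def pairwise_global_align(
    a: str,
    b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[str, str, float]:
    """Optimal global alignment of two proteins under BLOSUM62 affine gaps."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    S = np.array([[_residue_score(x, y) for y in b] for x in a])
    path, score = _affine_global(S, gap_open, gap_extend)
    out_a = "".join(a[i] if i >= 0 else GAP for i, _ in path)
    out_b = "".join(b[j] if j >= 0 else GAP for _, j in path)
    return out_a, out_b, score


def _merge(rows_a: list[str], rows_b: list[str],
           gap_open: float, gap_extend: float) -> list[str]:
    """Merge two sub-alignments by profile-profile global alignment."""
    fa, fb = _profile_freqs(rows_a), _profile_freqs(rows_b)
    S = fa @ BLOSUM62 @ fb.T
    path, _ = _affine_global(S, gap_open, gap_extend)
    merged_a = ["" for _ in rows_a]
    merged_b = ["" for _ in rows_b]
    for i, j in path:
        for r, row in enumerate(rows_a):
            merged_a[r] += row[i] if i >= 0 else GAP
        for r, row in enumerate(rows_b):
            merged_b[r] += row[j] if j >= 0 else GAP
    return merged_a + merged_b


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 minus the fraction of shared k-mers (multiset intersection)."""
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    from collections import Counter
    ca = Counter(a[i: i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i: i + k] for i in range(len(b) - k + 1))
    shared = sum((ca & cb).values())
    return 1.0 - shared / (min(len(a), len(b)) - k + 1)


def progressive_align(
    seqs: Sequence[SequenceRecord],
    family: str = "family",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Progressive alignment: k-mer distances, UPGMA guide tree, profile merges.

    Deterministic for a fixed input order.  A single sequence yields a
    one-row, gap-free alignment.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return Alignment(family, [seqs[0].id], [seqs[0].residues])
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kmer_distance(seqs[i].residues, seqs[j].residues)
    Z = linkage(squareform(D, checks=False), method="average")
    # cluster index -> (member indices, rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i].residues]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        merged = _merge(rows_a, rows_b, gap_open, gap_extend)
        clusters[n + step] = (idx_a + idx_b, merged)
    (order, rows), = clusters.values()
    # restore the input order of rows
    by_input = sorted(range(len(order)), key=lambda r: order[r])
    return Alignment(
        family,
        [seqs[order[r]].id for r in by_input],
        [rows[r] for r in by_input],
    )


def read_aligned_fasta(path, family: str = "family") -> Alignment:
    """Load a pre-aligned (gapped) FASTA as an :class:`Alignment`."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(family, ids, rows)


def write_aligned_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, row in zip(aln.ids, aln.rows):
            fh.write(f">{i}\n")
            for j in range(0, len(row), 60):
                fh.write(row[j: j + 60] + "\n")
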
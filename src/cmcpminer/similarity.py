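"""Local-alignment percent similarity and representative selection.

Percent identity between a mined bacterial protein and its human
cytokine counterpart is computed from an optimal Smith-Waterman local
alignment under BLOSUM62 with affine gaps (open 11, extend 1; a gap of
length k costs 11 + k), the identity being matches over alignment
columns.  The family representative is the member whose length is
closest to the human counterpart's, ties broken by higher identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cmcpminer.msa import AA_INDEX, BLOSUM62, GAP
from cmcpminer.seq_io import SequenceRecord

GAP_OPEN = 11.0
GAP_EXTEND = 1.0


@dataclass
class SimilarityRecord:
    cmcp_id: str
    human_id: str
    percent_identity: float
    alignment_length: int
    score: float
    aligned_a: str = ""
    aligned_b: str = ""
    flagged: bool = False  # no positive-scoring local alignment


def _score(a: str, b: str) -> float:
    ia, ib = AA_INDEX.get(a), AA_INDEX.get(b)
    if ia is None or ib is None:
        return 0.0
    return float(BLOSUM62[ia, ib])


def smith_waterman(
    a: str, b: str,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> tuple[str, str, float, tuple[int, int], tuple[int, int]]:
    """Optimal local alignment of two proteins.

    Returns (aligned_a, aligned_b, score, (a_start, a_end), (b_start,
    b_end)) with 0-based half-open spans on each input; empty alignment
    and zero score when no positive-scoring alignment exists.  A gap of
    length k costs ``gap_open + k * gap_extend``.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    NEG = -1e30
    ia = np.array([AA_INDEX.get(c, -1) for c in a])
    ib = np.array([AA_INDEX.get(c, -1) for c in b])
    Sx = np.zeros((n, m))
    ok = (ia >= 0)[:, None] & (ib >= 0)[None, :]
    Sx[ok] = BLOSUM62[np.clip(ia, 0, None)[:, None],
                      np.clip(ib, 0, None)[None, :]][ok]
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    go_ge = gap_open + gap_extend
    jm = np.arange(m)
    for i in range(1, n + 1):
        prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]),
                          Y[i - 1, :-1])
        M[i, 1:] = np.maximum(np.maximum(prev, 0.0) + Sx[i - 1, :], 0.0)
        X[i, 1:] = np.maximum(M[i - 1, 1:] - go_ge, X[i - 1, 1:] - gap_extend)
        runmax = np.maximum.accumulate(M[i, :-1] - go_ge + jm * gap_extend)
        Y[i, 1:] = runmax - jm * gap_extend
    best = float(M.max())
    if best <= 0:
        return "", "", 0.0, (0, 0), (0, 0)
    bi, bj = np.unravel_index(int(M.argmax()), M.shape)
    # value-based traceback from the best match cell
    out_a, out_b = [], []
    i, j, state = int(bi), int(bj), 0  # 0=M, 1=X, 2=Y
    tol = 1e-9
    while True:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = M[i, j] - Sx[i - 1, j - 1]
            i, j = i - 1, j - 1
            if prev <= tol:
                break
            if abs(M[i, j] - prev) < tol:
                state = 0
            elif abs(X[i, j] - prev) < tol:
                state = 1
            else:
                state = 2
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            val = X[i, j]
            i -= 1
            state = 0 if abs(M[i, j] - go_ge - val) < tol else 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            state = 0 if abs(M[i, j] - go_ge - val) < tol else 2
    out_a.reverse()
    out_b.reverse()
    return "".join(out_a), "".join(out_b), float(best), (i, int(bi)), (j, int(bj))


def local_align_identity(a: SequenceRecord, b: SequenceRecord) -> SimilarityRecord:
    """Percent identity of the optimal local alignment of two proteins."""
    al_a, al_b, score, _, _ = smith_waterman(a.residues, b.residues)
    if not al_a:
        return SimilarityRecord(
            cmcp_id=a.id, human_id=b.id, percent_identity=0.0,
            alignment_length=0, score=0.0, flagged=True,
        )
    cols = len(al_a)
    matches = sum(x == y and x != GAP for x, y in zip(al_a, al_b))
    return SimilarityRecord(
        cmcp_id=a.id, human_id=b.id,
        percent_identity=100.0 * matches / cols,
        alignment_length=cols, score=score,
        aligned_a=al_a, aligned_b=al_b,
    )


def select_representative(
    members: Sequence[SequenceRecord],
    human_ref: SequenceRecord,
    mode: str = "length",
) -> SequenceRecord:
    """Pick the family representative relative to the human counterpart.

    ``mode="length"`` (default): the member whose length is closest to
    the human reference's, ties broken by higher local percent identity,
    then input order.  ``mode="identity"``: the member with maximal
    percent identity outright.
    """
    if not members:
        raise ValueError("no members to choose from")
    if mode not in {"length", "identity"}:
        raise ValueError(f"unknown mode {mode!r}")
    ident = {m.id: local_align_identity(m, human_ref).percent_identity
             for m in members}
    if mode == "identity":
        return max(members, key=lambda m: ident[m.id])
    best = min(
        enumerate(members),
        key=lambda t: (abs(len(t[1]) - len(human_ref)), -ident[t[1].id], t[0]),
    )
    return best[1]


def write_similarity_table(records: Sequence[SimilarityRecord], path) -> None:
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["cmcp_id", "human_id", "pct_identity", "aln_len", "score"])
        for r in records:
            w.writerow([r.cmcp_id, r.human_id, f"{r.percent_identity:.2f}",
                        r.alignment_length, f"{r.score:.1f}"])
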
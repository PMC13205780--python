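"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives the quantity it checks from first principles
(path enumeration, scalar dynamic programming, all-pairs rule
application) without sharing code with the package's implementations.
"""

from __future__ import annotations

import math

import numpy as np

from cmcpminer.msa import AA, AA_INDEX, BLOSUM62


def enumerate_forward(hmm, seq: str) -> float:
    """Forward log-odds by explicit enumeration of every state path."""
    contribs = _path_contributions(hmm, seq)
    return math.log2(sum(contribs))


def enumerate_viterbi(hmm, seq: str) -> float:
    """Best-path log-odds by explicit enumeration of every state path."""
    contribs = _path_contributions(hmm, seq)
    return math.log2(max(contribs))


def _path_contributions(hmm, seq: str) -> list[float]:
    idx = [AA_INDEX.get(c, 20) for c in seq]
    n, L = len(idx), hmm.L
    eta = n / (n + 2.0)
    odds = hmm.match_p / hmm.background  # match emission odds vs background
    ends: list[tuple[int, float]] = []

    def walk(state: str, k: int, pos: int, w: float) -> None:
        # state entered at model position k having consumed pos residues
        if state == "M":
            if pos >= n:
                return
            x = idx[pos]
            w = w * (1.0 if x == 20 else odds[k, x])
            pos += 1
            if k == L - 1:
                ends.append((pos, w))
                return
            walk("M", k + 1, pos, w * hmm.t_mm[k])
            walk("I", k, pos, w * hmm.t_mi[k])
            walk("D", k + 1, pos, w * hmm.t_md[k])
        elif state == "I":
            if pos >= n:
                return
            pos += 1  # insert emits at background: odds factor 1
            walk("M", k + 1, pos, w * hmm.t_im[k])
            walk("I", k, pos, w * hmm.t_ii[k])
        else:  # D
            if k == L - 1:
                ends.append((pos, w))
                return
            walk("M", k + 1, pos, w * hmm.t_dm[k])
            walk("D", k + 1, pos, w * hmm.t_dd[k])

    contribs = []
    for i in range(n + 1):  # residues absorbed by the N flank
        ends = []
        walk("M", 0, i, hmm.t_bm)
        walk("D", 0, i, hmm.t_bd)
        for endpos, w in ends:
            m = n - endpos  # residues absorbed by the C flank
            contribs.append(w * eta ** (i + m) * (1 - eta) ** 2)
    return contribs


def _pair_score(x: str, y: str) -> float:
    ix, iy = AA_INDEX.get(x), AA_INDEX.get(y)
    if ix is None or iy is None:
        return 0.0
    return float(BLOSUM62[ix, iy])


def brute_global_score(a: str, b: str, go: float = 10.0, ge: float = 0.5) -> float:
    """Scalar affine-gap global alignment DP (gap cost go + (L-1)*ge)."""
    n, m = len(a), len(b)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + (j - 1) * ge)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _pair_score(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, Y[i, j - 1] - ge, X[i, j - 1] - go)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def brute_local_score(a: str, b: str, go: float = 11.0, ge: float = 1.0) -> float:
    """Scalar Smith-Waterman DP (gap of length k costs go + k*ge)."""
    n, m = len(a), len(b)
    NEG = -1e30
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _pair_score(a[i - 1], b[j - 1])
            M[i, j] = max(max(M[i - 1, j - 1], X[i - 1, j - 1],
                              Y[i - 1, j - 1], 0.0) + s, 0.0)
            X[i, j] = max(M[i - 1, j] - go - ge, X[i - 1, j] - ge)
            Y[i, j] = max(M[i, j - 1] - go - ge, Y[i, j - 1] - ge)
            best = max(best, M[i, j])
    return float(best)


def brute_cluster(seqs, identity_c: float, coverage_aS: float,
                  identity_fn) -> dict[str, str]:
    """All-pairs re-application of the greedy best-cluster rule.

    ``identity_fn(a, b) -> (identity, coverage_of_shorter)`` is supplied
    by the caller so the oracle shares only the *rule*, not the
    alignment code under test.
    """
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    reps: list[int] = []
    membership: dict[str, str] = {}
    for i in order:
        best_rep, best_ident = None, -1.0
        for r in reps:
            ident, cov = identity_fn(seqs[i].residues, seqs[r].residues)
            if ident >= identity_c and cov >= coverage_aS and ident > best_ident:
                best_rep, best_ident = r, ident
        if best_rep is None:
            reps.append(i)
            membership[seqs[i].id] = seqs[i].id
        else:
            membership[seqs[i].id] = seqs[best_rep].id
    return membership


def random_toy_hmm(rng: np.random.Generator, L: int):
    """A random, fully stochastic profile HMM for oracle comparisons."""
    from cmcpminer.profile_hmm import ProfileHMM, BACKGROUND

    def simplex(k):
        v = rng.random(k) + 0.05
        return v / v.sum()

    mp = np.stack([simplex(20) for _ in range(L)])
    tmm = np.zeros(L - 1); tmi = np.zeros(L - 1); tmd = np.zeros(L - 1)
    tim = np.zeros(L - 1); tii = np.zeros(L - 1)
    tdm = np.zeros(L - 1); tdd = np.zeros(L - 1)
    for k in range(L - 1):
        tmm[k], tmi[k], tmd[k] = simplex(3)
        tim[k], tii[k] = simplex(2)
        tdm[k], tdd[k] = simplex(2)
    bm, bd = simplex(2)
    return ProfileHMM(
        family="toy", match_p=mp, insert_p=BACKGROUND.copy(),
        background=BACKGROUND.copy(),
        t_mm=tmm, t_mi=tmi, t_md=tmd, t_im=tim, t_ii=tii,
        t_dm=tdm, t_dd=tdd, t_bm=float(bm), t_bd=float(bd),
    )
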
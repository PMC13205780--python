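"""Profile hidden Markov models for cytokine family search.

A Plan-7-style architecture with match (M), insert (I) and delete (D)
states per consensus position, scored in *glocal* mode: the full model
must be traversed, but the target sequence may carry unmodelled flanking
residues absorbed by self-looping N/C states that emit at background
frequency.  All scoring is log-odds in bits (log2 of model probability
over an i.i.d. background null), computed in log space with
log-sum-exp; the forward score sums over all state paths and the
Viterbi score takes the single best path.

Statistical significance uses a Gumbel (type-I extreme value) fit to
forward scores of i.i.d. background decoys:

    E(s) = n_eff * (1 - exp(-exp(-lambda * (s - mu))))

where ``n_eff`` is the number of targets scanned.  The fit is a plain
maximum-likelihood Gumbel fit; no attempt is made to reproduce HMMER's
internal calibration bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gumbel_r

from cmcpminer.msa import AA, AA_INDEX, Alignment, GAP

FORMAT_VERSION = 1

#: Background amino-acid frequencies (Robinson & Robinson 1991), AA order.
BACKGROUND = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

SCORE_FLOOR = -1e6  # bits; underflow clamp

_NEG = -np.inf


def _aa_indices(seq: str) -> np.ndarray:
    """Map a protein string to indices 0..19; any other symbol -> 20 (X)."""
    return np.array([AA_INDEX.get(c, 20) for c in seq.upper()], dtype=np.intp)


@dataclass
class Calibration:
    """Extreme-value calibration of decoy forward scores.

    Below the fit threshold ``tau`` the tail probability follows the
    Gumbel form ``1 - exp(-exp(-lam * (s - mu)))``; above ``tau`` a
    generalized-Pareto peaks-over-threshold fit refines the tail, with
    shape ``xi`` capturing the lighter-than-exponential decay profile
    scores show at finite target length (``xi = 0`` recovers the pure
    Gumbel/exponential tail).  The two pieces agree at ``tau``.
    """

    lam: float            # Gumbel scale parameter (>0)
    mu: float             # Gumbel location
    n_eff: int            # effective search-space size (targets scanned)
    tau: float = np.inf   # POT threshold; +inf = pure Gumbel
    p_tau: float = 0.0    # tail mass above tau
    xi: float = 0.0       # GPD shape
    sigma: float = 1.0    # GPD scale

    def tail_probability(self, bit_score: float | np.ndarray) -> np.ndarray:
        s = np.asarray(bit_score, float)
        gumbel = -np.expm1(-np.exp(-self.lam * (s - self.mu)))
        if not np.isfinite(self.tau):
            return gumbel
        from scipy.stats import genpareto
        gpd = self.p_tau * genpareto.sf(s - self.tau, self.xi, scale=self.sigma)
        # negligible exponential floor keeps the tail strictly decreasing
        # beyond a negative-shape GPD's finite endpoint
        floor = self.p_tau * 1e-15 * np.exp(-self.lam * np.maximum(s - self.tau, 0.0))
        return np.where(s <= self.tau, gumbel, np.maximum(gpd, floor))

    def evalue(self, bit_score: float | np.ndarray) -> float | np.ndarray:
        return self.n_eff * self.tail_probability(bit_score)


@dataclass
class HmmHit:
    """A single model-vs-target hit from a scan."""

    family: str
    target_id: str
    bit_score: float
    evalue: float


@dataclass
class ProfileHMM:
    family: str
    match_p: np.ndarray          # (L, 20) match emission probabilities
    insert_p: np.ndarray         # (20,) insert emissions (background)
    background: np.ndarray       # (20,)
    # inter-position transitions, length L-1 each (position k -> k+1)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    t_bm: float                  # begin -> M1
    t_bd: float                  # begin -> D1
    calibration: Optional[Calibration] = None
    match_columns: list[int] = field(default_factory=list)

    @property
    def L(self) -> int:
        return self.match_p.shape[0]

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("profile HMM needs at least one match state")
        if not np.allclose(self.match_p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.isclose(self.t_bm + self.t_bd, 1.0, atol=1e-9):
            raise ValueError("begin transitions must sum to 1")
        for trio in zip(self.t_mm, self.t_mi, self.t_md):
            if not np.isclose(sum(trio), 1.0, atol=1e-9):
                raise ValueError("M outgoing transitions must sum to 1")
        if self.t_im.size and not np.allclose(self.t_im + self.t_ii, 1.0, atol=1e-9):
            raise ValueError("I outgoing transitions must sum to 1")
        if self.t_dm.size and not np.allclose(self.t_dm + self.t_dd, 1.0, atol=1e-9):
            raise ValueError("D outgoing transitions must sum to 1")

    # -- log-space views (cached lazily) ---------------------------------
    def _logs(self):
        if not hasattr(self, "_log_cache"):
            with np.errstate(divide="ignore"):
                lm = np.log2(self.match_p / self.background)       # (L, 20)
                lm = np.hstack([lm, np.zeros((self.L, 1))])        # X column
                logs = dict(
                    lm=lm,
                    mm=np.log2(self.t_mm), mi=np.log2(self.t_mi),
                    md=np.log2(self.t_md), im=np.log2(self.t_im),
                    ii=np.log2(self.t_ii), dm=np.log2(self.t_dm),
                    dd=np.log2(self.t_dd),
                    bm=np.log2(self.t_bm) if self.t_bm > 0 else _NEG,
                    bd=np.log2(self.t_bd) if self.t_bd > 0 else _NEG,
                )
            self._log_cache = logs
        return self._log_cache

    def consensus(self) -> str:
        """Highest-probability residue at each match position."""
        return "".join(AA[i] for i in self.match_p.argmax(axis=1))

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        d = {
            "format_version": FORMAT_VERSION,
            "family": self.family,
            "L": self.L,
            "match_p": self.match_p.tolist(),
            "insert_p": self.insert_p.tolist(),
            "background": self.background.tolist(),
            "transitions": {
                "mm": self.t_mm.tolist(), "mi": self.t_mi.tolist(),
                "md": self.t_md.tolist(), "im": self.t_im.tolist(),
                "ii": self.t_ii.tolist(), "dm": self.t_dm.tolist(),
                "dd": self.t_dd.tolist(), "bm": self.t_bm, "bd": self.t_bd,
            },
            "match_columns": self.match_columns,
            "calibration": (
                None if self.calibration is None else
                {"lambda": self.calibration.lam, "mu": self.calibration.mu,
                 "n_eff": self.calibration.n_eff, "tau": self.calibration.tau,
                 "p_tau": self.calibration.p_tau, "xi": self.calibration.xi,
                 "sigma": self.calibration.sigma}
            ),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        d = json.loads(text)
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format {d.get('format_version')!r}")
        t = d["transitions"]
        cal = d.get("calibration")
        return cls(
            family=d["family"],
            match_p=np.array(d["match_p"], float),
            insert_p=np.array(d["insert_p"], float),
            background=np.array(d["background"], float),
            t_mm=np.array(t["mm"], float), t_mi=np.array(t["mi"], float),
            t_md=np.array(t["md"], float), t_im=np.array(t["im"], float),
            t_ii=np.array(t["ii"], float), t_dm=np.array(t["dm"], float),
            t_dd=np.array(t["dd"], float), t_bm=float(t["bm"]), t_bd=float(t["bd"]),
            calibration=None if cal is None else Calibration(
                lam=cal["lambda"], mu=cal["mu"], n_eff=cal["n_eff"],
                tau=cal.get("tau", np.inf), p_tau=cal.get("p_tau", 0.0),
                xi=cal.get("xi", 0.0), sigma=cal.get("sigma", 1.0)),
            match_columns=list(d.get("match_columns", [])),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ProfileHMM":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_profile(
    alignment: Alignment,
    pseudocount_weight: float = 1.0,
    max_gap_fraction: float = 0.5,
    background: np.ndarray = BACKGROUND,
) -> ProfileHMM:
    """Estimate a profile HMM from a multiple alignment.

    Columns with gap fraction <= ``max_gap_fraction`` become match
    states; the rest are insert columns.  Match emissions use a
    background-weighted pseudocount:

        P(a | k) = (n_ka + w * bg_a) / (N_k + w)

    with observed count ``n_ka``, column occupancy ``N_k`` and weight
    ``w = pseudocount_weight``.  Transitions are estimated from the
    observed per-row state paths with a uniform pseudocount of ``w``
    split over each state's outgoing set.  Insert emissions equal the
    background (so inserts are score-neutral).
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    w = pseudocount_weight
    match_cols = [j for j in range(alignment.ncol)
                  if alignment.gap_fraction(j) <= max_gap_fraction]
    if not match_cols:
        raise ValueError("no consensus columns: every column exceeds the gap threshold")
    L = len(match_cols)
    is_match = set(match_cols)

    # emissions
    match_p = np.zeros((L, 20))
    for k, j in enumerate(match_cols):
        counts = np.zeros(20)
        for r in alignment.rows:
            idx = AA_INDEX.get(r[j])
            if idx is not None:
                counts[idx] += 1.0
        occ = counts.sum()
        match_p[k] = (counts + w * background) / (occ + w)

    # transitions, counted over per-row state paths
    c_mm = np.zeros(max(L - 1, 0)); c_mi = np.zeros(max(L - 1, 0))
    c_md = np.zeros(max(L - 1, 0)); c_im = np.zeros(max(L - 1, 0))
    c_ii = np.zeros(max(L - 1, 0)); c_dm = np.zeros(max(L - 1, 0))
    c_dd = np.zeros(max(L - 1, 0))
    c_bm = 0.0; c_bd = 0.0
    for row in alignment.rows:
        states = ["M" if row[j] != GAP else "D" for j in match_cols]
        # insert residue counts between consecutive match columns
        ins = np.zeros(max(L - 1, 0))
        for k in range(L - 1):
            lo, hi = match_cols[k], match_cols[k + 1]
            ins[k] = sum(1 for j in range(lo + 1, hi)
                         if j not in is_match and row[j] != GAP)
        if states[0] == "M":
            c_bm += 1
        else:
            c_bd += 1
        for k in range(L - 1):
            cur, nxt = states[k], states[k + 1]
            n_ins = int(ins[k]) if cur == "M" else 0  # no D->I in Plan 7
            if cur == "M":
                if n_ins > 0:
                    c_mi[k] += 1
                    c_ii[k] += n_ins - 1
                    c_im[k] += 1  # I -> next (counted as I->M; D-next folded in)
                elif nxt == "M":
                    c_mm[k] += 1
                else:
                    c_md[k] += 1
            else:
                if nxt == "M":
                    c_dm[k] += 1
                else:
                    c_dd[k] += 1

    def _norm2(a, b):
        tot = a + b + w
        return (a + w / 2) / tot, (b + w / 2) / tot

    t_bm, t_bd = _norm2(c_bm, c_bd)
    tot_m = c_mm + c_mi + c_md + w
    t_mm = (c_mm + w / 3) / tot_m
    t_mi = (c_mi + w / 3) / tot_m
    t_md = (c_md + w / 3) / tot_m
    t_im, t_ii = _norm2(c_im, c_ii) if L > 1 else (np.zeros(0), np.zeros(0))
    t_dm, t_dd = _norm2(c_dm, c_dd) if L > 1 else (np.zeros(0), np.zeros(0))

    return ProfileHMM(
        family=alignment.family,
        match_p=match_p,
        insert_p=background.copy(),
        background=background.copy(),
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=np.asarray(t_im), t_ii=np.asarray(t_ii),
        t_dm=np.asarray(t_dm), t_dd=np.asarray(t_dd),
        t_bm=t_bm, t_bd=t_bd,
        match_columns=match_cols,
    )


def _flank_params(n: int) -> tuple[float, float]:
    """Self-loop and exit log2 probabilities of the N/C flank states."""
    eta = n / (n + 2.0)
    return np.log2(eta) if eta > 0 else _NEG, np.log2(1.0 - eta)


def forward_scores(hmm: ProfileHMM, seqs: Sequence[str]) -> np.ndarray:
    """Forward log-odds bit scores for a batch of protein sequences.

    Sequences are grouped by length internally so the dynamic program
    is vectorised across same-length targets.
    """
    out = np.empty(len(seqs))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        if not s:
            raise ValueError("cannot score an empty sequence")
        by_len.setdefault(len(s), []).append(i)
    for n, idxs in by_len.items():
        batch = np.stack([_aa_indices(seqs[i]) for i in idxs])
        out[np.array(idxs)] = _forward_batch(hmm, batch)
    return out


def forward_score(hmm: ProfileHMM, seq: str) -> float:
    """Forward (all-paths) log-odds score of one sequence, in bits."""
    return float(forward_scores(hmm, [seq])[0])


def _forward_batch(hmm: ProfileHMM, idx: np.ndarray) -> np.ndarray:
    g = hmm._logs()
    nseq, n = idx.shape
    L = hmm.L
    loop, exit_ = _flank_params(n)
    lm = g["lm"]

    M = np.full((nseq, L), _NEG)
    I = np.full((nseq, L), _NEG)
    D = np.full((nseq, L), _NEG)
    # row 0: no residue emitted yet; B reachable with prob (1 - eta)
    N = np.zeros(nseq)
    B = N + exit_
    D[:, 0] = B + g["bd"]
    for k in range(1, L):
        D[:, k] = D[:, k - 1] + g["dd"][k - 1]
    E = D[:, L - 1].copy()
    C = E.copy()

    for i in range(n):
        x = idx[:, i]
        em = lm[:, x].T                                    # (nseq, L)
        newM = np.full((nseq, L), _NEG)
        newM[:, 0] = em[:, 0] + B + g["bm"]
        if L > 1:
            prev = np.logaddexp2(
                M[:, :-1] + g["mm"],
                np.logaddexp2(I[:, :-1] + g["im"], D[:, :-1] + g["dm"]),
            )
            newM[:, 1:] = em[:, 1:] + prev
        newI = np.full((nseq, L), _NEG)
        if L > 1:
            newI[:, :-1] = np.logaddexp2(M[:, :-1] + g["mi"], I[:, :-1] + g["ii"])
        N = N + loop
        B = N + exit_
        newD = np.full((nseq, L), _NEG)
        newD[:, 0] = B + g["bd"]
        for k in range(1, L):
            newD[:, k] = np.logaddexp2(
                newM[:, k - 1] + g["md"][k - 1], newD[:, k - 1] + g["dd"][k - 1]
            )
        M, I, D = newM, newI, newD
        E = np.logaddexp2(M[:, L - 1], D[:, L - 1])
        C = np.logaddexp2(C + loop, E)

    return np.maximum(C + exit_, SCORE_FLOOR)


def viterbi(hmm: ProfileHMM, seq: str) -> tuple[list[tuple], float]:
    """Best state path and its log-odds bit score.

    Path elements are ``("N",)``, ``("B",)``, ``("M", k)``, ``("I", k)``,
    ``("D", k)``, ``("E",)``, ``("C",)`` with 1-based position k.  Ties
    break M > D > I.
    """
    g = hmm._logs()
    idx = _aa_indices(seq)
    n, L = len(idx), hmm.L
    loop, exit_ = _flank_params(n)
    lm = g["lm"]

    NEG = _NEG
    M = np.full((n + 1, L), NEG); I = np.full((n + 1, L), NEG)
    D = np.full((n + 1, L), NEG)
    ptrM = np.zeros((n + 1, L), dtype=np.int8)  # 0=B,1=M,2=D,3=I
    ptrI = np.zeros((n + 1, L), dtype=np.int8)  # 1=M,3=I
    ptrD = np.zeros((n + 1, L), dtype=np.int8)  # 0=B,1=M,2=D
    Nst = np.full(n + 1, NEG); E = np.full(n + 1, NEG); C = np.full(n + 1, NEG)
    fromC = np.zeros(n + 1, dtype=np.int8)      # 0 = from E, 1 = C loop
    fromE = np.zeros(n + 1, dtype=np.int8)      # 1 = M_L, 2 = D_L

    Nst[0] = 0.0
    B0 = Nst[0] + exit_
    D[0, 0] = B0 + g["bd"]; ptrD[0, 0] = 0
    for k in range(1, L):
        D[0, k] = D[0, k - 1] + g["dd"][k - 1]; ptrD[0, k] = 2
    E[0] = D[0, L - 1]; fromE[0] = 2
    C[0] = E[0]; fromC[0] = 0

    for i in range(1, n + 1):
        Nst[i] = Nst[i - 1] + loop
        B_prev = Nst[i - 1] + exit_
        x = idx[i - 1]
        for k in range(L):
            em = lm[k, x]
            if k == 0:
                M[i, 0] = em + B_prev + g["bm"]; ptrM[i, 0] = 0
            else:
                cand = (
                    (M[i - 1, k - 1] + g["mm"][k - 1], 1),
                    (D[i - 1, k - 1] + g["dm"][k - 1], 2),
                    (I[i - 1, k - 1] + g["im"][k - 1], 3),
                )
                best = max(cand, key=lambda t: t[0])
                M[i, k] = em + best[0]; ptrM[i, k] = best[1]
            if k < L - 1:
                cand = (
                    (M[i - 1, k] + g["mi"][k], 1),
                    (I[i - 1, k] + g["ii"][k], 3),
                )
                best = max(cand, key=lambda t: t[0])
                I[i, k] = best[0]; ptrI[i, k] = best[1]
        B_i = Nst[i] + exit_
        D[i, 0] = B_i + g["bd"]; ptrD[i, 0] = 0
        for k in range(1, L):
            cand = (
                (M[i, k - 1] + g["md"][k - 1], 1),
                (D[i, k - 1] + g["dd"][k - 1], 2),
            )
            best = max(cand, key=lambda t: t[0])
            D[i, k] = best[0]; ptrD[i, k] = best[1]
        if M[i, L - 1] >= D[i, L - 1]:
            E[i] = M[i, L - 1]; fromE[i] = 1
        else:
            E[i] = D[i, L - 1]; fromE[i] = 2
        if E[i] >= C[i - 1] + loop:
            C[i] = E[i]; fromC[i] = 0
        else:
            C[i] = C[i - 1] + loop; fromC[i] = 1

    score = float(max(C[n] + exit_, SCORE_FLOOR))

    # traceback
    path: list[tuple] = []
    i = n
    while fromC[i] == 1:
        path.append(("C",))
        i -= 1
    path.append(("C",))
    path.append(("E",))
    state = "M" if fromE[i] == 1 else "D"
    k = L - 1
    while True:
        path.append((state, k + 1))
        if state == "M":
            p = ptrM[i, k]
            i -= 1
            if p == 0:
                break
            state = {1: "M", 2: "D", 3: "I"}[int(p)]
            k -= 1
        elif state == "D":
            p = ptrD[i, k]
            if p == 0:
                break
            state = {1: "M", 2: "D"}[int(p)]
            k -= 1
        else:  # I
            p = ptrI[i, k]
            i -= 1
            state = {1: "M", 3: "I"}[int(p)]
    path.append(("B",))
    for _ in range(i):
        path.append(("N",))
    path.append(("N",))
    path.reverse()
    return path, score


def viterbi_score(hmm: ProfileHMM, seq: str) -> float:
    return viterbi(hmm, seq)[1]


def calibrate(
    hmm: ProfileHMM,
    decoy_length: int,
    n_decoys: int = 1000,
    seed: int = 0,
    n_eff: int = 1,
    tail_fraction: float = 0.10,
    method: str = "pot",
) -> ProfileHMM:
    """Fit E-value parameters from i.i.d. background decoy scores.

    Decoys of ``decoy_length`` are drawn from the model's background
    composition and forward-scored.  The default ``pot`` method fits
    the exceedances over the upper ``tail_fraction`` quantile by
    maximum likelihood: an exponential rate gives the Gumbel (lambda,
    mu) and a generalized-Pareto fit supplies the finite-length shape
    correction.  ``method="gumbel"`` instead fits a plain Gumbel to the
    full score sample (noticeably conservative deep in the tail).
    ``n_eff`` (targets in the intended scan) may be updated at scan
    time.  The model is modified in place and returned.
    """
    if n_decoys < 100:
        raise ValueError("need at least 100 decoys for a stable fit")
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    decoys = ["".join(rng.choice(list(AA), size=decoy_length, p=hmm.background))
              for _ in range(n_decoys)]
    scores = forward_scores(hmm, decoys)
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate decoy score variance; cannot calibrate")
    if method == "gumbel":
        loc, scale = gumbel_r.fit(scores)
        hmm.calibration = Calibration(lam=1.0 / scale, mu=float(loc),
                                      n_eff=int(n_eff))
        return hmm
    if method != "pot":
        raise ValueError(f"unknown calibration method {method!r}")
    tau = float(np.quantile(scores, 1.0 - tail_fraction))
    exc = scores[scores > tau] - tau
    if exc.size < 10 or exc.std() < 1e-12:
        raise ValueError("too few or degenerate tail exceedances; "
                         "increase n_decoys or tail_fraction")
    lam = 1.0 / float(exc.mean())          # exponential-tail ML rate
    # Gumbel location consistent with the tail mass at tau:
    # 1 - exp(-exp(-lam (tau - mu))) = p_tau
    mu = tau + np.log(-np.log1p(-tail_fraction)) / lam
    from scipy.stats import genpareto
    xi, _, sigma = genpareto.fit(exc, floc=0)
    hmm.calibration = Calibration(
        lam=lam, mu=float(mu), n_eff=int(n_eff),
        tau=tau, p_tau=tail_fraction, xi=float(xi), sigma=float(sigma),
    )
    return hmm


def evalue(hmm: ProfileHMM, bit_score: float, n_eff: Optional[int] = None) -> float:
    """E-value of a bit score under the model's Gumbel calibration."""
    if hmm.calibration is None:
        raise ValueError(f"model {hmm.family!r} is not calibrated")
    cal = hmm.calibration
    if n_eff is not None:
        cal = Calibration(cal.lam, cal.mu, n_eff)
    return float(cal.evalue(bit_score))
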
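"""Cross-validation-driven curation of cytokine family models.

Each family model is evaluated by K-fold cross-validation: the members
are evenly and randomly partitioned into K subsets; for every fold the
model is rebuilt from the other K-1 subsets and applied to the held-out
members.  Fold accuracy is

    A_i = C_i / T_i

the number of held-out members retrieved at E < 0.01 over the held-out
set size, and the summary is the mean fold accuracy

    A_avg = (1/K) * sum_i A_i .

Curation then iteratively removes putative confounders — members that
fit the family model poorly — and repeats cross-validation until the
model both exceeds the target mean accuracy (strictly above 50% by
default) and retains no member scoring below background (log-odds < 0
bits against the full-family model).  Families that never converge are
flagged and excluded from downstream mining.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from cmcpminer.msa import progressive_align
from cmcpminer.profile_hmm import build_profile, calibrate, evalue, forward_scores
from cmcpminer.seq_io import SequenceRecord

#: members scoring below this many bits against their own family model
#: are pruning candidates even when A_avg already meets the target
OUTLIER_BITS = 0.0

MIN_FAMILY_SIZE = 6  # eligibility: strictly more than 5 members


@dataclass
class CytokineFamily:
    """A named set of member protein sequences for one cytokine."""

    name: str
    members: list[SequenceRecord]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def subset(self, indices: Sequence[int]) -> "CytokineFamily":
        return CytokineFamily(self.name, [self.members[i] for i in indices])


@dataclass
class FoldAssignment:
    K: int
    fold_of: dict[int, int]  # member index -> fold id in 1..K
    seed: int

    def fold_members(self, k: int) -> list[int]:
        return [i for i, f in self.fold_of.items() if f == k]


@dataclass
class IterationRecord:
    fold_C: list[int]
    fold_T: list[int]
    fold_A: list[float]
    A_avg: float
    removed_ids: list[str]
    fold_seed: int
    failed_folds: list[int] = field(default_factory=list)


@dataclass
class CurationReport:
    family: str
    history: list[IterationRecord]
    converged: bool
    reason: str
    seed: int

    @property
    def iterations(self) -> int:
        return len(self.history)

    @property
    def A_avg(self) -> float:
        return self.history[-1].A_avg

    @property
    def removed_ids(self) -> list[str]:
        return [rid for it in self.history for rid in it.removed_ids]

    def to_json(self) -> str:
        return json.dumps({
            "family": self.family,
            "converged": self.converged,
            "reason": self.reason,
            "seed": self.seed,
            "iterations": self.iterations,
            "A_avg": self.A_avg,
            "history": [asdict(h) for h in self.history],
        }, indent=2)


def fold_accuracy(C: int, T: int) -> float:
    """Fraction of held-out members correctly retrieved, C/T."""
    if T < 1:
        raise ValueError("test-set size must be at least 1")
    if not 0 <= C <= T:
        raise ValueError("correct count must lie in [0, T]")
    return C / T


def kfold_partition(n: int, K: int = 10, seed: int = 0) -> FoldAssignment:
    """Evenly and randomly partition n members into K folds.

    Fold sizes differ by at most one; the assignment is reproducible
    under ``seed``.
    """
    if K < 2:
        raise ValueError("need at least 2 folds")
    if n < K:
        raise ValueError(f"family too small for {K} folds (n={n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = {int(idx): (pos % K) + 1 for pos, idx in enumerate(perm)}
    return FoldAssignment(K=K, fold_of=fold_of, seed=seed)


def _fold_seed(master_seed: int, iteration: int) -> int:
    return (master_seed * 1000003 + iteration) % (2**31 - 1)


def cross_validate(
    family: CytokineFamily,
    K: int = 10,
    evalue_max: float = 0.01,
    seed: int = 0,
    calibration_decoys: int = 500,
    pseudocount_weight: float = 1.0,
) -> IterationRecord:
    """K-fold cross-validation of one family's model.

    For each fold the remaining members are aligned, a profile HMM is
    built and calibrated, and the held-out members are scanned; a
    held-out member counts as correctly predicted when its E-value
    (with n_eff = held-out set size) is below ``evalue_max``.
    """
    if len(family) < MIN_FAMILY_SIZE:
        raise ValueError(
            f"family {family.name!r} has {len(family)} members; "
            f"eligibility requires more than 5"
        )
    assign = kfold_partition(len(family), K=K, seed=seed)
    fold_C, fold_T, fold_A, failed = [], [], [], []
    for k in range(1, K + 1):
        test_idx = assign.fold_members(k)
        train_idx = [i for i in range(len(family)) if assign.fold_of[i] != k]
        train = [family.members[i] for i in train_idx]
        test = [family.members[i] for i in test_idx]
        try:
            aln = progressive_align(train, family=family.name)
            hmm = build_profile(aln, pseudocount_weight=pseudocount_weight)
        except ValueError:
            failed.append(k)
            continue
        decoy_len = int(np.median([len(t) for t in test]))
        calibrate(hmm, decoy_length=decoy_len, n_decoys=calibration_decoys,
                  seed=_fold_seed(seed, k), n_eff=len(test))
        scores = forward_scores(hmm, [t.residues for t in test])
        C = int(sum(evalue(hmm, s) < evalue_max for s in scores))
        fold_C.append(C)
        fold_T.append(len(test))
        fold_A.append(fold_accuracy(C, len(test)))
    if not fold_A:
        raise ValueError(f"family {family.name!r}: every fold failed to build")
    return IterationRecord(
        fold_C=fold_C, fold_T=fold_T, fold_A=fold_A,
        A_avg=float(np.mean(fold_A)), removed_ids=[], fold_seed=seed,
        failed_folds=failed,
    )


def _member_scores(family: CytokineFamily, seed: int,
                   pseudocount_weight: float) -> np.ndarray:
    """Forward log-odds of every member against the full-family model."""
    aln = progressive_align(family.members, family=family.name)
    hmm = build_profile(aln, pseudocount_weight=pseudocount_weight)
    return forward_scores(hmm, [m.residues for m in family.members])


def curate_family(
    family: CytokineFamily,
    target_accuracy: float = 0.5,
    max_iter: int = 20,
    K: int = 10,
    evalue_max: float = 0.01,
    seed: int = 0,
    prune_fraction: float = 0.05,
    calibration_decoys: int = 500,
    pseudocount_weight: float = 1.0,
) -> tuple[CytokineFamily, CurationReport]:
    """Iteratively prune confounders until the family model generalises.

    Each iteration runs :func:`cross_validate` and scores every member
    against the model built from the whole current family.  The loop
    stops (converged) when A_avg strictly exceeds ``target_accuracy``
    and no member scores below :data:`OUTLIER_BITS`; otherwise the
    ceil(``prune_fraction`` x n) lowest-scoring members (at least one,
    restricted to sub-background members when the accuracy target is
    already met) are removed and the loop repeats.  Pruning that drives
    the family to 5 or fewer members, or exhausting ``max_iter``, flags
    the family as non-converged.
    """
    current = family
    history: list[IterationRecord] = []
    converged = False
    reason = "max_iter reached without convergence"
    for it in range(1, max_iter + 1):
        if len(current) < K:
            reason = f"family too small for {K} folds"
            break
        fold_seed = _fold_seed(seed, it)
        record = cross_validate(
            current, K=K, evalue_max=evalue_max, seed=fold_seed,
            calibration_decoys=calibration_decoys,
            pseudocount_weight=pseudocount_weight,
        )
        scores = _member_scores(current, fold_seed, pseudocount_weight)
        outliers = np.flatnonzero(scores < OUTLIER_BITS)
        if record.A_avg > target_accuracy and outliers.size == 0:
            history.append(record)
            converged = True
            reason = "A_avg above target and no sub-background members"
            break
        n_prune = max(1, math.ceil(prune_fraction * len(current)))
        order = np.argsort(scores, kind="stable")
        if record.A_avg > target_accuracy:
            # accuracy target met: only sub-background members are suspect
            candidates = [i for i in order if scores[i] < OUTLIER_BITS]
        else:
            candidates = list(order)
        drop = set(candidates[:n_prune])
        record.removed_ids = [current.members[i].id for i in sorted(drop)]
        history.append(record)
        keep = [i for i in range(len(current)) if i not in drop]
        current = current.subset(keep)
        if len(current) < MIN_FAMILY_SIZE:
            reason = "family shrank to 5 or fewer members"
            break
    if not history:
        raise ValueError(
            f"family {family.name!r} too small for {K}-fold cross-validation")
    report = CurationReport(
        family=family.name, history=history, converged=converged,
        reason=reason, seed=seed,
    )
    return current, report
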
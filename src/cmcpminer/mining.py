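"""Scanning translated ORFs against family models and redundancy clustering.

The scan scores every (model, protein) pair with the forward algorithm
and keeps hits with E-value below the threshold (0.01 by default), the
effective search-space size being the number of proteins scanned.
Redundant hit sequences are collapsed by greedy incremental clustering
in the CD-HIT style: sequences are taken longest-first, each joining
the best-matching existing cluster whose representative aligns locally
at >= 95% identity over the alignment columns while covering >= 90% of
the shorter sequence, or founding a new cluster.  Unlike CD-HIT no
k-mer pre-filter is used — identities come from actual local
alignments, affordable at this scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

from cmcpminer.profile_hmm import HmmHit, ProfileHMM, evalue, forward_scores
from cmcpminer.seq_io import OrfRecord, SequenceRecord
from cmcpminer.similarity import smith_waterman, GAP


@dataclass
class ProvenancedHit:
    family: str
    target_id: str
    bit_score: float
    evalue: float
    contig_id: str
    start: int
    end: int
    strand: str


@dataclass
class MiningResult:
    hits: list[ProvenancedHit]
    representatives: list[SequenceRecord]
    cluster_membership: dict[str, str]  # member id -> representative id


def scan_proteins(
    models: Sequence[ProfileHMM],
    proteins: Sequence[SequenceRecord],
    evalue_max: float = 0.01,
) -> list[HmmHit]:
    """Score all proteins against all models; keep hits at E < evalue_max.

    Every model's effective search-space size is set to the number of
    proteins scanned.  Hits are sorted by (family, evalue).
    """
    hits: list[HmmHit] = []
    n_eff = len(proteins)
    seqs = [p.residues for p in proteins]
    for hmm in models:
        if hmm.calibration is None:
            raise ValueError(f"model {hmm.family!r} is not calibrated")
        if not proteins:
            continue
        scores = forward_scores(hmm, seqs)
        for p, s in zip(proteins, scores):
            e = evalue(hmm, float(s), n_eff=n_eff)
            if e < evalue_max:
                hits.append(HmmHit(family=hmm.family, target_id=p.id,
                                   bit_score=float(s), evalue=float(e)))
    hits.sort(key=lambda h: (h.family, h.evalue, h.target_id))
    return hits


def _identity_and_coverage(a: str, b: str) -> tuple[float, float]:
    """Local-alignment identity over columns and coverage of the shorter."""
    al_a, al_b, _, span_a, span_b = smith_waterman(a, b)
    if not al_a:
        return 0.0, 0.0
    cols = len(al_a)
    matches = sum(x == y and x != GAP for x, y in zip(al_a, al_b))
    short_len = min(len(a), len(b))
    short_span = (span_a if len(a) <= len(b) else span_b)
    coverage = (short_span[1] - short_span[0]) / short_len
    return matches / cols, coverage


def cluster_redundant(
    seqs: Sequence[SequenceRecord],
    identity_c: float = 0.95,
    short_coverage_aS: float = 0.9,
    best_cluster: bool = True,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy incremental redundancy clustering of protein sequences.

    Sequences are processed longest first (ties: input order).  A
    sequence joins a cluster when its local alignment to the cluster
    representative reaches ``identity_c`` identity over the alignment
    columns and covers at least ``short_coverage_aS`` of the shorter
    sequence.  With ``best_cluster`` (default) the qualifying cluster of
    highest identity is chosen; otherwise the first qualifying one.

    Returns the representatives (in founding order) and a mapping of
    every sequence id to its representative id (representatives map to
    themselves).
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    reps: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    for i in order:
        s = seqs[i]
        best_idx: Optional[int] = None
        best_ident = -1.0
        for r_idx, rep in enumerate(reps):
            ident, cov = _identity_and_coverage(s.residues, rep.residues)
            if ident >= identity_c and cov >= short_coverage_aS:
                if not best_cluster:
                    best_idx = r_idx
                    break
                if ident > best_ident:
                    best_ident, best_idx = ident, r_idx
        if best_idx is None:
            reps.append(s)
            membership[s.id] = s.id
        else:
            membership[s.id] = reps[best_idx].id
    return reps, membership


def attach_provenance(
    hits: Sequence[HmmHit],
    orfs: Sequence[OrfRecord],
    identity_c: float = 0.95,
    short_coverage_aS: float = 0.9,
) -> MiningResult:
    """Join hits to their ORF records and collapse redundant hit proteins."""
    by_id = {o.orf_id: o for o in orfs}
    for o in orfs:
        by_id.setdefault(o.protein.id, o)
    joined: list[ProvenancedHit] = []
    hit_proteins: dict[str, SequenceRecord] = {}
    for h in hits:
        o = by_id.get(h.target_id)
        if o is None:
            raise ValueError(f"hit target {h.target_id!r} has no ORF record")
        joined.append(ProvenancedHit(
            family=h.family, target_id=h.target_id,
            bit_score=h.bit_score, evalue=h.evalue,
            contig_id=o.contig_id, start=o.start, end=o.end, strand=o.strand,
        ))
        hit_proteins.setdefault(h.target_id, SequenceRecord(
            id=h.target_id, residues=o.protein.residues, alphabet="protein"))
    if hit_proteins:
        reps, membership = cluster_redundant(
            list(hit_proteins.values()), identity_c, short_coverage_aS)
    else:
        reps, membership = [], {}
    return MiningResult(hits=joined, representatives=reps,
                        cluster_membership=membership)


def write_hits_table(hits: Sequence[ProvenancedHit], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["family", "target_id", "contig", "start", "end",
                    "strand", "bit_score", "evalue"])
        for h in hits:
            w.writerow([h.family, h.target_id, h.contig_id, h.start, h.end,
                        h.strand, f"{h.bit_score:.2f}", f"{h.evalue:.3g}"])


def write_clusters_table(membership: dict[str, str], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["member_id", "representative_id"])
        for member, rep in sorted(membership.items()):
            w.writerow([member, rep])
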
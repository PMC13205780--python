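"""Synthetic inputs with exact ground truth for every pipeline stage.

Three generators emulate the statistical structure of the real inputs:

* protein families derived from a random seed sequence by independent
  per-site substitution, optionally spiked with unrelated background
  ("confounder") sequences — the situation the cross-validation
  curation stage must detect;
* contigs of random background DNA carrying planted in-frame,
  stop-flanked ORFs that reverse-translate family members with uniform
  synonymous codon choice (genetic code table 11);
* eight case/control cohorts of negative-binomial counts with planted
  log2 fold-change effects, variance mu + dispersion * mu^2, and
  per-sample depth factors.

Every generator is deterministic under the scenario's master seed;
stage seeds are derived from it by fixed offsets.  Truth tables are
exact and machine-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field


import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from cmcpminer.curation import CytokineFamily
from cmcpminer.profile_hmm import BACKGROUND
from cmcpminer.msa import AA
from cmcpminer.seq_io import SequenceRecord, reverse_complement

_TABLE11 = unambiguous_dna_by_id[11]
#: codon choices per amino acid under table 11 (stop codons excluded)
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in _TABLE11.forward_table.items():
    CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in CODONS_BY_AA:
    CODONS_BY_AA[aa].sort()

_SEED_FAMILY = 11
_SEED_GENOME = 23
_SEED_COHORT = 37


@dataclass
class SimScenario:
    """Parameters of one simulated study."""

    seed: int = 0
    # families
    n_families: int = 3
    family_size: int = 30
    protein_length: int = 60
    divergence: float = 0.10     # per-site substitution probability
    n_confounders: int = 0
    # genomes
    n_contigs: int = 10
    contig_length: int = 3000
    n_planted_orfs: int = 10
    # cohorts
    n_cohorts: int = 8
    n_case: int = 20
    n_control: int = 20
    n_features: int = 50
    planted_effects: dict[str, float] = dc_field(default_factory=dict)
    dispersion: float = 0.2      # NB dispersion: var = mu + disp * mu^2
    baseline_mean: float = 100.0
    depth_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length, p=BACKGROUND))


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Independent per-site substitution to a *different* background residue."""
    out = []
    aa_arr = np.array(list(AA))
    for c in seq:
        if rng.random() < divergence:
            i = AA.index(c)
            probs = BACKGROUND.copy()
            probs[i] = 0.0
            probs /= probs.sum()
            out.append(rng.choice(aa_arr, p=probs))
        else:
            out.append(c)
    return "".join(out)


@dataclass
class FamilyTruth:
    confounder_ids: list[str]
    root_protein: str


def simulate_family(
    scenario: SimScenario, name: str = "fam1", family_index: int = 0,
) -> tuple[CytokineFamily, FamilyTruth]:
    """One family of diverged members plus planted confounders.

    Returns the family and the ground truth (confounder ids and the
    common root protein).  Members derive from the root by per-site
    substitution at the scenario's divergence; confounders are i.i.d.
    background proteins.
    """
    rng = np.random.default_rng(scenario.seed + _SEED_FAMILY + 1000 * family_index)
    root = _random_protein(rng, scenario.protein_length)
    members = [
        SequenceRecord(id=f"{name}_m{i:03d}",
                       residues=_mutate(root, scenario.divergence, rng))
        for i in range(scenario.family_size)
    ]
    confounders = [
        SequenceRecord(id=f"{name}_c{i:03d}",
                       residues=_random_protein(rng, scenario.protein_length))
        for i in range(scenario.n_confounders)
    ]
    fam = CytokineFamily(name, members + confounders)
    return fam, FamilyTruth([c.id for c in confounders], root)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Encode a protein as DNA with uniformly chosen synonymous codons."""
    return "".join(rng.choice(CODONS_BY_AA[aa]) for aa in protein)


def simulate_genome(
    scenario: SimScenario,
    families: list[CytokineFamily],
    max_tries: int = 200,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Contigs of background DNA with planted stop-flanked family ORFs.

    Planted members are drawn round-robin across families; each is
    reverse-translated, flanked with TAA stops, and written at a random
    non-overlapping position and strand.  The truth table gives contig,
    1-based inclusive forward-strand coordinates of the stop-free codon
    run, strand, family, member id and protein.
    """
    rng = np.random.default_rng(scenario.seed + _SEED_GENOME)
    contigs = [
        list(rng.choice(["A", "C", "G", "T"], size=scenario.contig_length))
        for _ in range(scenario.n_contigs)
    ]
    occupied: list[list[tuple[int, int]]] = [[] for _ in contigs]
    truth_rows = []
    pool = [
        (fam.name, m)
        for k in range(max(len(f.members) for f in families))
        for fam in families
        for m in [fam.members[k]] if k < len(fam.members)
    ]
    for p in range(scenario.n_planted_orfs):
        fam_name, member = pool[p % len(pool)]
        cds = reverse_translate(member.residues, rng)
        insert = "TAA" + cds + "TAA"
        if len(insert) + 6 > scenario.contig_length:
            raise ValueError("contig too short for the planted ORF")
        placed = False
        for _ in range(max_tries):
            ci = int(rng.integers(scenario.n_contigs))
            # keep the insert on a fixed codon offset chosen at random
            pos = int(rng.integers(0, scenario.contig_length - len(insert)))
            if any(not (pos + len(insert) <= s or pos >= e)
                   for s, e in occupied[ci]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            seq = insert if strand == "+" else reverse_complement(insert)
            contigs[ci][pos: pos + len(insert)] = list(seq)
            occupied[ci].append((pos, pos + len(insert)))
            if strand == "+":
                start, end = pos + 4, pos + 3 + len(cds)
            else:
                start = pos + 4
                end = pos + 3 + len(cds)
            truth_rows.append({
                "contig": f"contig{ci:03d}",
                "start": start, "end": end, "strand": strand,
                "family": fam_name, "member_id": member.id,
                "protein": member.residues,
            })
            placed = True
            break
        if not placed:
            raise ValueError("could not place a planted ORF without overlap")
    records = [
        SequenceRecord(id=f"contig{i:03d}", residues="".join(c), alphabet="dna")
        for i, c in enumerate(contigs)
    ]
    return records, pd.DataFrame(truth_rows)


def simulate_cohorts(
    scenario: SimScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Eight case/control cohorts of NB counts with planted effects.

    Counts for feature i in sample j have mean
    ``baseline_i * depth_j * 2**(lfc_i * case_j)`` and variance
    ``mu + dispersion * mu**2``; depths are uniform in ``depth_range``.
    Returns (count matrix features x samples, sample metadata, truth
    effects mapping).
    """
    rng = np.random.default_rng(scenario.seed + _SEED_COHORT)
    features = [f"feat{i:04d}" for i in range(scenario.n_features)]
    effects = {f: scenario.planted_effects.get(f, 0.0) for f in features}
    unknown = set(scenario.planted_effects) - set(features)
    if unknown:
        raise ValueError(f"planted effects for unknown features: {sorted(unknown)}")
    baselines = rng.lognormal(np.log(scenario.baseline_mean), 0.5,
                              size=scenario.n_features)
    disp = scenario.dispersion
    r = 1.0 / disp
    cols, meta_rows = {}, []
    for c in range(1, scenario.n_cohorts + 1):
        for cond, n in (("case", scenario.n_case), ("control", scenario.n_control)):
            for s in range(n):
                sid = f"cohort{c}_{cond}{s:02d}"
                depth = rng.uniform(*scenario.depth_range)
                mu = baselines * depth
                if cond == "case":
                    mu = mu * np.power(2.0, np.array([effects[f] for f in features]))
                counts = rng.negative_binomial(r, r / (r + mu))
                cols[sid] = counts
                meta_rows.append({"sample_id": sid, "cohort": f"cohort{c}",
                                  "condition": cond,
                                  "library_size": int(counts.sum())})
    counts = pd.DataFrame(cols, index=features)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts, meta, effects
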
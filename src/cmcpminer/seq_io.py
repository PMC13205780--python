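"""Sequence records, FASTA I/O and stop-to-stop ORF extraction.

ORF extraction mirrors EMBOSS ``getorf -find 0``: every maximal stop-free
codon run in all six reading frames, bounded by stop codons or by the
contig ends, is reported — no initiator codon is required.  Translation
uses the bacterial/archaeal genetic code (NCBI table 11).  Runs that abut
a contig edge (partial ORFs) are included by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "XBZJUO*")
DNA_ALPHABET = set("ACGTN" + "RYSWKMBDHV")
STOP_CODONS_TABLE11 = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(nt: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return nt.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named sequence over the protein or DNA alphabet."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence body")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: symbols {sorted(bad)} outside {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OrfRecord:
    """An open reading frame located on a contig.

    Coordinates are 1-based inclusive on the forward strand (EMBOSS
    convention); ``frame`` is 1..3 within the strand the ORF lies on.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: SequenceRecord = field(repr=False)

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}|{self.start}-{self.end}({self.strand})"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.nt_length % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if len(self.protein) != self.nt_length // 3:
            raise ValueError("protein length inconsistent with nucleotide span")
        if "*" in self.protein.residues:
            raise ValueError("ORF protein contains a stop symbol")


def read_fasta(path: Union[str, Path], alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The first whitespace-delimited token of each header is the record id;
    the remainder is kept as the description.  Sequence is upper-cased.
    An empty file yields an empty list; a sequence body before the first
    header or an empty body raises :class:`ValueError`.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        # reject leading header-less sequence explicitly: Biopython skips it
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(f"{path}: sequence data before first FASTA header")
                break
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).replace(" ", "")
            if not seq:
                raise ValueError(f"{path}: record {rec.id!r} has empty sequence body")
            desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
            records.append(SequenceRecord(id=rec.id, residues=seq, description=desc, alphabet=alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def translate(nt: str, table: int = 11) -> str:
    """Translate a nucleotide string codon by codon under the given code.

    Internal stops render as ``*``; codons with ambiguous bases that
    cannot be resolved (e.g. containing N) render as ``X``.  Length must
    be a multiple of three.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    return str(Seq(nt).translate(table=table))


def _frame_runs(n_codons: int, stop_idx: list[int]) -> list[tuple[int, int]]:
    """Maximal stop-free codon runs [i, j) between stops/edges."""
    runs = []
    prev = 0
    for s in stop_idx + [n_codons]:
        if s > prev:
            runs.append((prev, s))
        prev = s + 1
    return runs


def extract_orfs(
    contig: SequenceRecord,
    min_nt: int = 150,
    table: int = 11,
    include_edges: bool = True,
) -> list[OrfRecord]:
    """Extract stop-to-stop ORFs of length ``>= min_nt`` from all six frames.

    Parameters
    ----------
    contig:
        DNA sequence record to scan.
    min_nt:
        Minimum ORF length in nucleotides (default 150 nt, i.e. 50 aa).
    include_edges:
        Whether runs truncated by the contig ends (no bounding stop) are
        reported; on by default.

    Returns
    -------
    list of :class:`OrfRecord` with forward-strand coordinates, ordered
    by strand then frame then position.
    """
    if contig.alphabet != "dna":
        raise ValueError("extract_orfs expects a DNA record")
    seq = contig.residues
    n = len(seq)
    orfs: list[OrfRecord] = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in (1, 2, 3):
            off = frame - 1
            n_codons = (n - off) // 3
            if n_codons == 0:
                continue
            stop_idx = [
                i for i in range(n_codons)
                if s[off + 3 * i: off + 3 * i + 3] in STOP_CODONS_TABLE11
            ]
            for a, b in _frame_runs(n_codons, stop_idx):
                nt_len = (b - a) * 3
                if nt_len < min_nt:
                    continue
                # a run starting at codon 0 or ending at the last codon has
                # no bounding stop on that side (contig-edge partial ORF)
                if not include_edges and (a == 0 or b == n_codons):
                    continue
                # positions on the scanned strand, 0-based [lo, hi)
                lo = off + 3 * a
                hi = off + 3 * b
                if strand == "+":
                    start, end = lo + 1, hi
                else:
                    start, end = n - hi + 1, n - lo
                prot = translate(s[lo:hi], table=table)
                orfs.append(
                    OrfRecord(
                        contig_id=contig.id,
                        start=start,
                        end=end,
                        strand=strand,
                        frame=frame,
                        protein=SequenceRecord(
                            id=f"{contig.id}|{start}-{end}({strand})",
                            residues=prot,
                            alphabet="protein",
                        ),
                    )
                )
    return orfs


def write_orf_table(orfs: Iterable[OrfRecord], path: Union[str, Path]) -> None:
    """Write an ORF table as TSV."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig_id", "start", "end", "strand", "frame", "nt_length"])
        for o in orfs:
            w.writerow([o.contig_id, o.start, o.end, o.strand, o.frame, o.nt_length])
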
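"""Sequence utilities for toxin-isoform comparison.

Covers the sequence-level plumbing of the actinoporin variability analysis:
FASTA I/O, translation of partial cDNAs, splicing of an Edman-degradation
N-terminal prefix onto the translated body to reconstruct the mature protein,
theoretical average molecular mass, and pairwise identity/difference counting
(on pre-aligned rows or after a deterministic global alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq


class Alphabet(str, Enum):
    PROTEIN = "protein"
    DNA = "dna"


GAP = "-"
AA_SYMBOLS = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_SYMBOLS = set("ACGTN")

# Average residue masses in Da (Expasy-style table); free water to close termini.
WATER_MASS = 18.0153
RESIDUE_AVG_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed; carries the offending line."""


class OverlapConflictError(ValueError):
    """Raised when the Edman prefix and the translated body disagree in their overlap."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence with a declared alphabet."""

    id: str
    seq: str
    alphabet: Alphabet = Alphabet.PROTEIN

    def __post_init__(self) -> None:
        allowed = (AA_SYMBOLS if self.alphabet is Alphabet.PROTEIN else DNA_SYMBOLS) | {GAP}
        bad = set(self.seq.upper()) - allowed
        if bad:
            raise ValueError(
                f"{self.id!r}: symbols {sorted(bad)} not in {self.alphabet.value} alphabet"
            )

    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MatureSequence:
    """Mature protein assembled from an Edman prefix and a cDNA-translated body."""

    edman_prefix: str
    translated_body: str
    full: str

    def __post_init__(self) -> None:
        if not self.full:
            raise ValueError("mature sequence is empty")
        if self.full != self.edman_prefix + self.translated_body:
            raise ValueError("full != prefix + body after overlap reconciliation")


@dataclass(frozen=True)
class PairwiseComparison:
    n_identical: int
    n_different: int
    n_aligned: int

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.n_identical / self.n_aligned


def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.PROTEIN) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving file order.

    Raises FastaParseError (with a line number) on an empty file or when the
    first non-blank line is not a header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: line 0: empty file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), alphabet=alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def translate_cds(cds: SequenceRecord, frame: int = 0) -> SequenceRecord:
    """Translate a coding nucleotide sequence with the standard genetic code.

    Translation stops at (and excludes) the first stop codon. Codons containing
    ``N`` translate to ``X``; any other ambiguity code is rejected.
    """
    if cds.alphabet is not Alphabet.DNA:
        raise ValueError("translate_cds requires a DNA record")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    nt = cds.seq.upper().replace(GAP, "")[frame:]
    if len(nt) < 3:
        raise ValueError("fewer than 3 nucleotides after frame offset")
    nt = nt[: len(nt) - len(nt) % 3]
    protein = str(Seq(nt).translate(to_stop=True))
    return SequenceRecord(id=cds.id, seq=protein, alphabet=Alphabet.PROTEIN)


def splice_mature(edman_prefix: str, translated: str, overlap: int = 0) -> MatureSequence:
    """Join an N-terminal Edman prefix onto a cDNA-translated body.

    ``overlap`` is the number of residues covered by both (the tail of the
    prefix and the head of the translated body, e.g. where degenerate primers
    covered part of the mature coding sequence). Overlapping residues must
    agree exactly; a mismatch raises OverlapConflictError naming the position.
    """
    if not edman_prefix or not translated:
        raise ValueError("both prefix and translated body must be non-empty")
    if overlap < 0 or overlap > min(len(edman_prefix), len(translated)):
        raise ValueError(f"overlap {overlap} out of range")
    if overlap:
        tail = edman_prefix[-overlap:]
        head = translated[:overlap]
        for i, (a, b) in enumerate(zip(tail, head)):
            if a != b:
                pos = len(edman_prefix) - overlap + i + 1
                raise OverlapConflictError(
                    f"prefix/body disagree at mature position {pos}: {a} vs {b}"
                )
    body = translated[overlap:]
    return MatureSequence(edman_prefix=edman_prefix, translated_body=body,
                          full=edman_prefix + body)


def average_mass(seq: SequenceRecord | str) -> float:
    """Theoretical average molecular mass of an unmodified protein, in Da.

    Sum of standard average residue masses plus one water (18.0153 Da). The
    empty sequence returns the mass of water alone.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if GAP in s:
        raise ValueError("gapped sequence has no defined mass")
    mass = WATER_MASS
    for aa in s.upper():
        try:
            mass += RESIDUE_AVG_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue symbol {aa!r}") from None
    return mass


def _global_align(a: str, b: str) -> tuple[str, str]:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    aln = aligner.align(a, b)[0]
    # rebuild gapped rows from the aligned block coordinates
    out_a, out_b = [], []
    prev_a = prev_b = 0
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        out_a.append(a[prev_a:sa]), out_b.append(GAP * (sa - prev_a))
        out_a.append(GAP * (sb - prev_b)), out_b.append(b[prev_b:sb])
        out_a.append(a[sa:ea]), out_b.append(b[sb:eb])
        prev_a, prev_b = ea, eb
    out_a.append(a[prev_a:]), out_b.append(GAP * (len(a) - prev_a))
    out_a.append(GAP * (len(b) - prev_b)), out_b.append(b[prev_b:])
    return "".join(out_a), "".join(out_b)


def pairwise_compare(a: SequenceRecord, b: SequenceRecord, mode: str = "aligned") -> PairwiseComparison:
    """Count identical/different positions between two sequences.

    mode="aligned" compares pre-aligned equal-length rows column by column;
    mode="global" first performs a deterministic Needleman–Wunsch alignment
    (BLOSUM62, gap open 10 / extend 0.5). Only columns where both rows carry a
    residue are counted, so the identity denominator excludes gapped columns.
    """
    if not a.seq or not b.seq:
        raise ValueError("empty sequence")
    if mode == "aligned":
        if len(a.seq) != len(b.seq):
            raise ValueError("aligned mode requires equal-length sequences")
        ra, rb = a.seq, b.seq
    elif mode == "global":
        ra, rb = _global_align(a.ungapped(), b.ungapped())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_id = n_diff = 0
    for x, y in zip(ra, rb):
        if x == GAP or y == GAP:
            continue
        if x == y:
            n_id += 1
        else:
            n_diff += 1
    return PairwiseComparison(n_identical=n_id, n_different=n_diff, n_aligned=n_id + n_diff)


def region_differences(a: SequenceRecord, b: SequenceRecord, start: int, end: int,
                       mode: str = "aligned") -> int:
    """Number of differing positions within a 1-based inclusive region.

    Positions are numbered on the ungapped first sequence (the reference):
    e.g. differences within the N-terminal helix, residues 1–29.
    """
    if start < 1 or start > end:
        raise ValueError(f"invalid region {start}..{end}")
    if mode == "aligned":
        ra, rb = a.seq, b.seq
        if len(ra) != len(rb):
            raise ValueError("aligned mode requires equal-length sequences")
    else:
        ra, rb = _global_align(a.ungapped(), b.ungapped())
    if end > len(ra) - ra.count(GAP):
        raise ValueError(f"region end {end} beyond reference length")
    n_diff = 0
    ref_pos = 0
    for x, y in zip(ra, rb):
        if x == GAP:
            continue
        ref_pos += 1
        if ref_pos < start:
            continue
        if ref_pos > end:
            break
        if x != y:  # a gap in the partner counts as a difference
            n_diff += 1
    return n_diff
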
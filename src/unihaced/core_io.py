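"""Sequence primitives and file I/O.

The alphabet used throughout is the 15-letter IUPAC nucleotide code.  Plain
read/reference sequences are restricted to ``A C G T N``; primers may carry
any degenerate code.  All coordinates in the package are 0-based half-open.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, ContractError, ParseError

# Degenerate IUPAC codes and the plain bases each one covers.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Minimal IUPAC code for every non-empty subset of {A,C,G,T}.
CODE_FOR_BASES: dict[frozenset[str], str] = {
    frozenset(bases): code for code, bases in IUPAC_CODES.items()
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(_COMPLEMENT)

NUC_ALPHABET = frozenset("ACGTN")
IUPAC_ALPHABET = frozenset(IUPAC_CODES)

#: edlib ``additionalEqualities`` making every degenerate code match the
#: plain bases it covers (used when a degenerate construct is aligned
#: against a plain read).
IUPAC_EQUALITIES: list[tuple[str, str]] = [
    (code, base)
    for code, bases in IUPAC_CODES.items()
    if len(bases) > 1
    for base in bases
]


def _check_alphabet(seq: str, alphabet: frozenset[str], what: str) -> None:
    if set(seq) <= alphabet:
        return
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise AlphabetError(
                f"invalid character {ch!r} at position {i} in {what}"
            )


@dataclass
class NucSeq:
    """A named nucleotide sequence with optional phred qualities.

    ``seq`` is uppercased on construction and restricted to ``A C G T N``;
    ``qual``, when present, must have one integer per base.
    """

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ContractError(f"sequence {self.id!r} is empty")
        _check_alphabet(self.seq, NUC_ALPHABET, f"sequence {self.id!r}")
        if self.qual is not None:
            if len(self.qual) != len(self.seq):
                raise ContractError(
                    f"sequence {self.id!r}: qual length {len(self.qual)} != "
                    f"seq length {len(self.seq)}"
                )
            if any(q < 0 for q in self.qual):
                raise ContractError(f"sequence {self.id!r}: negative phred score")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MitoRecord:
    """A reference mitogenome (or excerpt) with species label and features.

    Features are ``(name, start, end)`` tuples in 0-based half-open
    coordinates on the given strand.
    """

    accession: str
    species: str
    seq: NucSeq
    features: tuple[tuple[str, int, int], ...] = ()

    FEATURE_NAMES = frozenset(
        {"D-loop", "tRNA-Thr", "tRNA-Pro", "tRNA-Phe", "12S rRNA", "other"}
    )

    def __post_init__(self) -> None:
        n = len(self.seq)
        for name, start, end in self.features:
            if not (0 <= start < end <= n):
                raise ContractError(
                    f"{self.accession}: feature {name} [{start},{end}) outside "
                    f"sequence of length {n}"
                )
            if name not in self.FEATURE_NAMES:
                raise ContractError(f"{self.accession}: unknown feature {name!r}")

    def feature(self, name: str) -> tuple[int, int]:
        for fname, start, end in self.features:
            if fname == name:
                return start, end
        raise KeyError(name)


def expand_degenerate(primer: str) -> list[str]:
    """Enumerate every plain sequence consistent with a degenerate primer.

    The result is in deterministic lexicographic order and has length equal
    to the product of the per-position code cardinalities.
    """
    primer = primer.upper()
    _check_alphabet(primer, IUPAC_ALPHABET, "primer")
    choices = [IUPAC_CODES[c] for c in primer]
    return ["".join(p) for p in itertools.product(*choices)]


def degeneracy(primer: str) -> int:
    """Number of plain sequences a degenerate primer expands to."""
    primer = primer.upper()
    _check_alphabet(primer, IUPAC_ALPHABET, "primer")
    n = 1
    for c in primer:
        n *= len(IUPAC_CODES[c])
    return n


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (an involution)."""
    seq = seq.upper()
    _check_alphabet(seq, IUPAC_ALPHABET, "sequence")
    return seq.translate(_COMP_TABLE)[::-1]


_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    """``(length, op)`` pairs from an extended cigar (``= X I D``)."""
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def alignment_stats(cigar: str) -> tuple[int, int]:
    """Return ``(matches, alignment_length)`` for an extended cigar."""
    matches = 0
    length = 0
    for n, op in _CIGAR_RE.findall(cigar):
        length += int(n)
        if op == "=":
            matches += int(n)
    return matches, length


def percent_identity(
    a: str | NucSeq,
    b: str | NucSeq,
    mode: Literal["global", "semi-global"] = "global",
) -> float:
    """Identity of an optimal unit-cost alignment of two sequences.

    Identity is matches / alignment columns of an optimal edit-distance
    alignment (match 0, mismatch 1, indel 1).  In semi-global mode the
    shorter sequence is aligned as an infix of the longer one, so the
    unaligned ends of the longer sequence are not penalized.
    """
    sa = a.seq if isinstance(a, NucSeq) else a.upper()
    sb = b.seq if isinstance(b, NucSeq) else b.upper()
    if not sa or not sb:
        raise ContractError("percent_identity requires nonempty sequences")
    if mode == "global":
        # canonical argument order: among equally optimal alignments edlib's
        # traceback depends on which sequence is the query, so fix the order
        # to keep the statistic symmetric
        q, t = sorted((sa, sb), key=lambda s: (len(s), s))
        res = edlib.align(q, t, mode="NW", task="path")
    elif mode == "semi-global":
        query, target = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
        res = edlib.align(query, target, mode="HW", task="path")
    else:
        raise ContractError(f"unknown mode {mode!r}")
    matches, length = alignment_stats(res["cigar"])
    return matches / length


# ---------------------------------------------------------------------------
# FASTA / FASTQ / feature-table I/O (phred+33 for FASTQ)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucSeq]:
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(NucSeq(id=rec.id, seq=str(rec.seq)))
    except (ValueError, AlphabetError) as exc:
        raise ParseError(f"{path}: record {len(records) + 1}: {exc}") from exc
    return records


def write_fasta(records: Iterable[NucSeq], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[NucSeq]:
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            records.append(
                NucSeq(
                    id=rec.id,
                    seq=str(rec.seq),
                    qual=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except (ValueError, AlphabetError) as exc:
        raise ParseError(f"{path}: record {len(records) + 1}: {exc}") from exc
    return records


def write_fastq(records: Iterable[NucSeq], path: str | Path) -> None:
    seq_records = []
    for r in records:
        if r.qual is None:
            raise ContractError(f"record {r.id!r} has no qualities")
        sr = SeqRecord(Seq(r.seq), id=r.id, description="")
        sr.letter_annotations["phred_quality"] = list(r.qual)
        seq_records.append(sr)
    SeqIO.write(seq_records, str(path), "fastq")


def read_feature_table(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a TSV of ``accession, feature, start, end`` (0-based half-open).

    Returns a mapping accession -> list of (feature, start, end).
    """
    table: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.lower().startswith("accession")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            acc, name, start_s, end_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if not 0 <= start < end:
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval [{start},{end})"
                )
            table.setdefault(acc, []).append((name, start, end))
    return table


def write_feature_table(
    table: dict[str, list[tuple[str, int, int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tfeature\tstart\tend\n")
        for acc, feats in table.items():
            for name, start, end in feats:
                fh.write(f"{acc}\t{name}\t{start}\t{end}\n")
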
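"""Sequence records, coordinate arithmetic, strand handling and CDS translation.

Coordinates are exposed 1-based inclusive throughout the public API, matching
the ``start→end`` citation style used for fungal gene annotations (e.g. the
MAT1-2-1 intron I at 187→238 of JQ325153).  Internally, slicing converts to
0-based half-open once, in :func:`to_zero_based` / :func:`to_one_based`.

The genetic code is the standard nuclear code; the stop codons are
TAA, TGA and TAG.  Ambiguity bases other than N are rejected at parse time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")
STOP_CODONS = frozenset({"TAA", "TGA", "TAG"})

SENSE = "+"
ANTISENSE = "-"
_ARROW = {SENSE: "→", ANTISENSE: "←"}  # → and ←


class FastaFormatError(ValueError):
    """Raised for empty or malformed FASTA input."""


class AlphabetError(ValueError):
    """Raised when residues fall outside the declared alphabet."""


class CoordinateError(ValueError):
    """Raised for invalid 1-based interval coordinates."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention of printed report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def infer_alphabet(residues: str) -> str:
    letters = set(residues.upper())
    if letters <= NUCLEOTIDE_ALPHABET:
        return "nucleotide"
    if letters <= PROTEIN_ALPHABET:
        return "protein"
    raise AlphabetError(
        f"residues contain characters outside both alphabets: "
        f"{sorted(letters - (NUCLEOTIDE_ALPHABET | PROTEIN_ALPHABET))}"
    )


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence (residues stored upper-case)."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = ""

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise ValueError(f"record {self.id!r} has no residues")
        alphabet = self.alphabet or infer_alphabet(residues)
        if alphabet == "nucleotide":
            bad = set(residues) - NUCLEOTIDE_ALPHABET
        elif alphabet == "protein":
            bad = set(residues) - PROTEIN_ALPHABET
        else:
            raise ValueError(f"unknown alphabet {alphabet!r}")
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters {sorted(bad)} are not valid "
                f"{alphabet} residues (only N is accepted as an ambiguity base)"
            )
        object.__setattr__(self, "alphabet", alphabet)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a named sequence, with strand."""

    seq_id: str
    start: int
    end: int
    strand: str = SENSE

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise CoordinateError(
                f"invalid interval {self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.strand not in (SENSE, ANTISENSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        # "187→238" for sense, "187←238" for antisense
        return f"{self.start}{_ARROW[self.strand]}{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class TranslationResult:
    """Product of translating a CDS; ``arrested`` means an in-frame stop was hit."""

    protein: str
    arrested: bool
    stop_codon_ordinal: Optional[int] = None

    def __post_init__(self) -> None:
        if "*" in self.protein:
            raise ValueError("translated product must not contain '*'")
        if self.arrested and self.stop_codon_ordinal != len(self.protein) + 1:
            raise ValueError("stop ordinal inconsistent with product length")


# ---------------------------------------------------------------------------
# coordinate conversion


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start < 1 or start > end:
        raise CoordinateError(f"invalid 1-based interval {start}..{end}")
    return start - 1, end


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (inverse of :func:`to_zero_based`)."""
    if start0 < 0 or start0 >= end0:
        raise CoordinateError(f"invalid 0-based interval [{start0}, {end0})")
    return start0 + 1, end0


def interval_length(iv: GenomicInterval) -> int:
    """Nucleotide count of a 1-based inclusive interval (end - start + 1)."""
    return len(iv)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, alphabet: Optional[str] = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Duplicate ids are disambiguated with a numeric suffix and reported as a
    warning.  An empty file is a format error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id = rec.id
        if rec_id in seen:
            seen[rec_id] += 1
            new_id = f"{rec_id}.{seen[rec_id]}"
            warnings.warn(
                f"duplicate FASTA id {rec_id!r}; renamed to {new_id!r}", stacklevel=2
            )
            rec_id = new_id
        else:
            seen[rec_id] = 1
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec_id, residues=str(rec.seq), description=desc,
                           alphabet=alphabet or "")
        )
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                line_width: int = 60) -> None:
    """Write records as wrapped FASTA (default 60 columns)."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# strand handling and extraction


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    if not set(seq.upper()) <= NUCLEOTIDE_ALPHABET:
        raise AlphabetError("reverse_complement requires a nucleotide sequence")
    return str(Seq(seq.upper()).reverse_complement())


def extract_interval(rec: SequenceRecord, iv: GenomicInterval) -> str:
    """1-based inclusive slice of ``rec``; antisense intervals come back
    reverse-complemented."""
    if rec.alphabet != "nucleotide":
        raise AlphabetError("extract_interval operates on nucleotide records")
    if iv.end > len(rec):
        raise CoordinateError(
            f"interval {iv} exceeds record {rec.id!r} of length {len(rec)}"
        )
    s0, e0 = to_zero_based(iv.start, iv.end)
    segment = rec.residues[s0:e0]
    if iv.strand == ANTISENSE:
        return reverse_complement(segment)
    return segment


# ---------------------------------------------------------------------------
# translation


def translate_cds(cds: str, stop_policy: str = "arrest") -> TranslationResult:
    """Translate a CDS in frame 1 under the standard nuclear genetic code.

    ``arrest`` stops at the first in-frame TAA/TGA/TAG; ``read_through`` is a
    diagnostic mode that emits X for stop codons and never arrests.  A trailing
    partial codon (1-2 nt) is ignored.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS must be at least one codon long")
    if stop_policy not in ("arrest", "read_through"):
        raise ValueError(f"unknown stop policy {stop_policy!r}")
    n_codons = len(cds) // 3
    residues: list[str] = []
    for i in range(n_codons):
        codon = cds[3 * i: 3 * i + 3]
        if codon in STOP_CODONS:
            if stop_policy == "arrest":
                return TranslationResult(
                    protein="".join(residues), arrested=True, stop_codon_ordinal=i + 1
                )
            residues.append("X")
        elif "N" in codon:
            residues.append("X")
        else:
            residues.append(str(Seq(codon).translate()))
    return TranslationResult(protein="".join(residues), arrested=False)
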
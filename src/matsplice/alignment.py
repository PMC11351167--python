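"""Pairwise alignment and identity statistics.

A thin, deterministic layer over :class:`Bio.Align.PairwiseAligner` providing
the three modes used throughout the toolkit:

* ``global``     -- Needleman-Wunsch with affine gaps;
* ``semiglobal`` -- global alignment with free (unpenalised) end gaps in both
  sequences, the mode used to map transcripts onto genes and query genes onto
  assemblies;
* ``local``      -- Smith-Waterman.

Gap cost convention: a gap of length L costs ``gap_open + L * gap_extend``
(BLAST-style "existence + per-residue extension").  Defaults mirror the BLAST
family programs the comparisons stand in for: nucleotide +2/-3 with gaps
-5/-2, protein BLOSUM62 with gaps -11/-1.

Identity is counted over aligned columns; in semiglobal mode the free end-gap
columns are excluded from the column count, which is the closest analogue of
BLAST's "identities / alignment length".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align

from .seqcore import (
    GenomicInterval,
    infer_alphabet,
    round_half_up,
)

MODES = ("global", "semiglobal", "local")

#: inputs larger than this (per side) are refused by the exact DP and must go
#: through the k-mer-anchored banded path (see :mod:`matsplice.occurrence`).
LARGE_SEQUENCE_LIMIT = 5_000_000
ANCHOR_K = 31


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for :func:`pairwise_align`.

    ``gap_open``/``gap_extend`` are penalties (<= 0); a length-L gap scores
    ``gap_open + L * gap_extend``.  When ``protein_matrix`` is set the
    match/mismatch scores are ignored in favour of the named substitution
    matrix.
    """

    mode: str = "semiglobal"
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    protein_matrix: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.protein_matrix is None and self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")

    @classmethod
    def nucleotide(cls, mode: str = "semiglobal") -> "AlignmentParams":
        return cls(mode=mode)

    @classmethod
    def protein(cls, mode: str = "global") -> "AlignmentParams":
        return cls(mode=mode, gap_open=-11.0, gap_extend=-1.0,
                   protein_matrix="BLOSUM62")


@dataclass(frozen=True)
class AlignmentResult:
    """One pairwise alignment with its identity bookkeeping.

    ``aligned_query``/``aligned_subject`` are equal-length gapped strings.
    ``aligned_columns`` excludes free end-gap columns in semiglobal mode.
    ``query_span``/``subject_span`` are the 1-based inclusive coordinates of
    the aligned (gap-stripped) region in each input.
    """

    aligned_query: str
    aligned_subject: str
    score: float
    identities: int
    aligned_columns: int
    query_span: GenomicInterval
    subject_span: GenomicInterval
    mode: str = "global"

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings must have equal length")
        if self.identities > self.aligned_columns:
            raise ValueError("identities cannot exceed aligned columns")


def _build_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    if params.protein_matrix is not None:
        aligner.substitution_matrix = Align.substitution_matrices.load(
            params.protein_matrix
        )
    else:
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    # our convention: gap of length L costs open + L*extend, so the first gap
    # residue costs open+extend
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    if params.mode == "local":
        aligner.mode = "local"
    else:
        aligner.mode = "global"
        if params.mode == "semiglobal":
            try:
                aligner.end_insertion_score = 0.0
                aligner.end_deletion_score = 0.0
            except AttributeError:  # Biopython < 1.86 spelling
                aligner.target_end_gap_score = 0.0
                aligner.query_end_gap_score = 0.0
    return aligner


def _end_gap_trim(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    """Column range [lo, hi) after stripping leading/trailing end gaps."""
    n = len(aligned_a)
    lead_a = n - len(aligned_a.lstrip("-"))
    lead_b = n - len(aligned_b.lstrip("-"))
    trail_a = n - len(aligned_a.rstrip("-"))
    trail_b = n - len(aligned_b.rstrip("-"))
    lo = max(lead_a, lead_b)
    hi = n - max(trail_a, trail_b)
    return lo, max(lo, hi)


def pairwise_align(a: str, b: str, params: Optional[AlignmentParams] = None
                   ) -> AlignmentResult:
    """Optimal affine-gap alignment of query ``a`` against subject ``b``.

    Ties between co-optimal alignments are broken deterministically by taking
    the first traceback in the aligner's fixed exploration order, so repeated
    runs produce byte-identical reports.
    """
    params = params or AlignmentParams.nucleotide()
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    a, b = a.upper(), b.upper()
    if params.protein_matrix is None and infer_alphabet(a) != infer_alphabet(b):
        # a matrix makes the protein mode explicit; otherwise both sequences
        # must carry the same alphabet (ACGT-only proteins are undecidable
        # and treated as nucleotide)
        raise ValueError("query and subject must share an alphabet")
    if max(len(a), len(b)) > LARGE_SEQUENCE_LIMIT:
        raise ValueError(
            f"inputs exceed {LARGE_SEQUENCE_LIMIT} residues; use the anchored "
            "screening path in matsplice.occurrence"
        )
    aligner = _build_aligner(params)
    alignments = aligner.align(a, b)
    try:
        alignment = alignments[0]
    except IndexError:
        # local mode with no positive-scoring pair: the empty alignment
        return _summarise("", "", 0.0, params.mode)
    aligned_a, aligned_b = alignment[0], alignment[1]
    return _summarise(aligned_a, aligned_b, float(alignment.score), params.mode)


def _summarise(aligned_a: str, aligned_b: str, score: float, mode: str
               ) -> AlignmentResult:
    if mode == "semiglobal":
        lo, hi = _end_gap_trim(aligned_a, aligned_b)
    else:
        lo, hi = 0, len(aligned_a)
    identities = 0
    columns = hi - lo
    for x, y in zip(aligned_a[lo:hi], aligned_b[lo:hi]):
        if x == y and x != "-":
            identities += 1

    def span(aligned: str, other_id: str) -> GenomicInterval:
        before = len(aligned[:lo].replace("-", ""))
        inside = len(aligned[lo:hi].replace("-", ""))
        if inside == 0:
            inside = 1  # degenerate: no residues inside trimmed range
        return GenomicInterval(other_id, before + 1, before + inside)

    return AlignmentResult(
        aligned_query=aligned_a,
        aligned_subject=aligned_b,
        score=score,
        identities=identities,
        aligned_columns=columns,
        query_span=span(aligned_a, "query"),
        subject_span=span(aligned_b, "subject"),
        mode=mode,
    )


def percent_identity(res: AlignmentResult, denominator: str = "columns") -> float:
    """Identity percentage, rounded half-up to 0.1.

    ``columns`` divides by aligned columns (internal gaps included, free end
    gaps excluded); ``shorter_seq`` divides by the shorter gap-stripped
    sequence length.
    """
    if denominator == "columns":
        denom = res.aligned_columns
    elif denominator == "shorter_seq":
        denom = min(
            len(res.aligned_query.replace("-", "")),
            len(res.aligned_subject.replace("-", "")),
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("zero-length denominator for percent identity")
    return round_half_up(100.0 * res.identities / denom, 1)


# ---------------------------------------------------------------------------
# BLAST-like text layouts


def format_pairwise(res: AlignmentResult, width: int = 60) -> str:
    """Plain-text stacked alignment with a match line, BLAST-style."""
    out = []
    qa, sa = res.aligned_query, res.aligned_subject
    match = "".join(
        "|" if x == y and x != "-" else " " for x, y in zip(qa, sa)
    )
    for i in range(0, len(qa), width):
        out.append(f"Query  {qa[i:i + width]}")
        out.append(f"       {match[i:i + width]}")
        out.append(f"Sbjct  {sa[i:i + width]}")
        out.append("")
    return "\n".join(out)


def format_tabular(query_id: str, subject_id: str, res: AlignmentResult) -> str:
    """Single outfmt-6-like TSV line (identity, length, spans, score)."""
    fields = [
        query_id,
        subject_id,
        f"{percent_identity(res):.1f}",
        str(res.aligned_columns),
        str(res.query_span.start),
        str(res.query_span.end),
        str(res.subject_span.start),
        str(res.subject_span.end),
        f"{res.score:.1f}",
    ]
    return "\t".join(fields)
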
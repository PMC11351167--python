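"""Presence/absence screening of query genes against assemblies.

Screening is anchored: exact 31-mers shared between query and subject seed a
candidate region, which is then refined by semiglobal alignment of the query
against the seeded subject window (both strands are tried).  This keeps the
screen desk-scale for multi-megabase assemblies while behaving like a
stringent nucleotide BLAST for the 95-100% identity hits that matter for
mating-type gene screening.  A query is called present when the best hit
reaches both the identity and the coverage thresholds; assemblies sharing no
anchor k-mer with the query are called absent without alignment.

Multi-record assemblies are screened record by record; a gene split across
two contigs is reported through the combined coverage of its partial hits.
Occurrence matrices print absences as the em-dash-style mark used in
published presence/absence tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .alignment import (
    ANCHOR_K,
    AlignmentParams,
    AlignmentResult,
    pairwise_align,
    percent_identity,
)
from .seqcore import (
    ANTISENSE,
    SENSE,
    GenomicInterval,
    SequenceRecord,
    reverse_complement,
    round_half_up,
)

ABSENT_MARK = "―"


@dataclass(frozen=True)
class OccurrenceParams:
    identity_threshold: float = 90.0
    coverage_threshold: float = 80.0
    k: int = ANCHOR_K
    window_margin: int = 200

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("anchor k-mer must be at least 8")


@dataclass(frozen=True)
class PartialHit:
    subject_id: str
    identity: float
    query_range: tuple[int, int]  # 1-based inclusive on the query
    location: GenomicInterval
    score: float


@dataclass(frozen=True)
class OccurrenceCall:
    query_id: str
    subject_id: str
    identity: float
    coverage: float
    present: bool
    location: Optional[GenomicInterval] = None
    partial_hits: tuple[PartialHit, ...] = ()

    def cell(self) -> str:
        return f"{self.identity:.1f}" if self.present else ABSENT_MARK


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def shares_kmer(a: str, b: str, k: int = ANCHOR_K) -> bool:
    """True if the sequences (either strand of ``b``) share an exact k-mer."""
    index = _kmer_index(a.upper(), k)
    for s in (b.upper(), reverse_complement(b)):
        for i in range(len(s) - k + 1):
            if s[i:i + k] in index:
                return True
    return False


def _anchor_diagonals(query_index: dict[str, list[int]], subject: str, k: int
                      ) -> list[tuple[int, int]]:
    """(subject_pos, query_pos) anchor pairs (0-based)."""
    anchors = []
    for j in range(len(subject) - k + 1):
        kmer = subject[j:j + k]
        for i in query_index.get(kmer, ()):
            anchors.append((j, i))
    return anchors


def _screen_record(query: str, query_index: dict[str, list[int]],
                   record: SequenceRecord, params: OccurrenceParams
                   ) -> Optional[PartialHit]:
    best: Optional[PartialHit] = None
    qlen = len(query)
    for strand in (SENSE, ANTISENSE):
        subject = (record.residues if strand == SENSE
                   else reverse_complement(record.residues))
        anchors = _anchor_diagonals(query_index, subject, params.k)
        if not anchors:
            continue
        lo = max(0, min(j - i for j, i in anchors) - params.window_margin)
        hi = min(
            len(subject),
            max(j - i for j, i in anchors) + qlen + params.window_margin,
        )
        window = subject[lo:hi]
        res = pairwise_align(query, window,
                             AlignmentParams.nucleotide("semiglobal"))
        identity = percent_identity(res)
        q_start, q_end = res.query_span.start, res.query_span.end
        # window coordinates -> oriented subject -> original record coordinates
        s_start = lo + res.subject_span.start
        s_end = lo + res.subject_span.end
        if strand == ANTISENSE:
            n = len(record.residues)
            s_start, s_end = n - s_end + 1, n - s_start + 1
        hit = PartialHit(
            subject_id=record.id,
            identity=identity,
            query_range=(q_start, q_end),
            location=GenomicInterval(record.id, s_start, s_end, strand),
            score=res.score,
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def screen_assembly(query: SequenceRecord,
                    subjects: Sequence[SequenceRecord],
                    params: Optional[OccurrenceParams] = None,
                    subject_id: str = "") -> OccurrenceCall:
    """Best anchored hit of ``query`` across a (multi-record) assembly."""
    params = params or OccurrenceParams()
    if not subjects:
        raise ValueError("empty subject set")
    if query.alphabet != "nucleotide":
        raise ValueError("occurrence screening is nucleotide-only")
    label = subject_id or subjects[0].id
    q = query.residues
    query_index = _kmer_index(q, params.k)

    hits = []
    for rec in subjects:
        hit = _screen_record(q, query_index, rec, params)
        if hit is not None:
            hits.append(hit)
    if not hits:
        return OccurrenceCall(
            query_id=query.id, subject_id=label,
            identity=0.0, coverage=0.0, present=False,
        )
    hits.sort(key=lambda h: h.score, reverse=True)
    covered: set[int] = set()
    weighted = 0.0
    weight = 0
    for h in hits:
        span = set(range(h.query_range[0], h.query_range[1] + 1))
        new = span - covered
        if not new:
            continue  # redundant hit over an already-covered region
        covered |= span
        weighted += h.identity * len(span)
        weight += len(span)
    coverage = round_half_up(100.0 * len(covered) / len(q), 1)
    identity = round_half_up(weighted / weight, 1)
    present = (identity >= params.identity_threshold
               and coverage >= params.coverage_threshold)
    return OccurrenceCall(
        query_id=query.id, subject_id=label,
        identity=identity, coverage=coverage, present=present,
        location=hits[0].location, partial_hits=tuple(hits),
    )


@dataclass
class OccurrenceMatrix:
    """Subjects (assemblies) x query genes grid of occurrence calls."""

    subjects: list[str]
    queries: list[str]
    calls: dict[tuple[str, str], OccurrenceCall]

    def call(self, subject_id: str, query_id: str) -> OccurrenceCall:
        return self.calls[(subject_id, query_id)]

    def to_frame(self) -> pd.DataFrame:
        data = {
            q: [self.calls[(s, q)].cell() for s in self.subjects]
            for q in self.queries
        }
        return pd.DataFrame(data, index=self.subjects)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="subject")

    def to_json(self, path: str | Path) -> None:
        payload = {
            f"{s}|{q}": {
                "identity": c.identity,
                "coverage": c.coverage,
                "present": c.present,
                "location": str(c.location) if c.location else None,
                "strand": c.location.strand if c.location else None,
            }
            for (s, q), c in self.calls.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def occurrence_matrix(queries: Sequence[SequenceRecord],
                      subjects: dict[str, Sequence[SequenceRecord]],
                      params: Optional[OccurrenceParams] = None
                      ) -> OccurrenceMatrix:
    """One :class:`OccurrenceCall` per (assembly, query gene) pair."""
    params = params or OccurrenceParams()
    calls = {}
    for sid, records in subjects.items():
        for query in queries:
            calls[(sid, query.id)] = screen_assembly(
                query, records, params, subject_id=sid
            )
    return OccurrenceMatrix(
        subjects=list(subjects), queries=[q.id for q in queries], calls=calls
    )
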
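"""Transcript-to-gene mapping: splice status, intron phase, indels, truncation.

This is the analytical core of the toolkit.  A transcript is mapped onto its
annotated gene by semiglobal alignment (free end gaps, both orientations
tried); every annotated intron is then classified as spliced, retained,
partial or unresolved; exonic insertions/deletions and 5'/3' transcript
truncations are collected; and the mutant protein product is predicted by
rebuilding the effective mRNA and translating it under the arrest policy.

Intron phase follows the standard convention: phase 0 introns fall between
codons, phase 1 after the first nucleotide of a codon, phase 2 after the
second.  A retained phase-1 or phase-2 intron therefore disrupts both the
reading frame and the interrupted codon, which is why stop triplets inside a
retained intron arrest translation (the MAT1-2-1 intron I situation).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from .alignment import AlignmentParams, pairwise_align
from .seqcore import (
    ANTISENSE,
    SENSE,
    GenomicInterval,
    SequenceRecord,
    TranslationResult,
    reverse_complement,
    translate_cds,
)

INTRON_STATUSES = ("spliced", "retained", "partial", "unresolved")
PRODUCT_CLASSES = (
    "full", "n_truncated", "middle_truncated", "arrested", "frameshifted",
    "compound",
)


class GeneModelError(ValueError):
    """Raised for inconsistent exon/CDS annotations."""


class UnrelatedTranscriptError(ValueError):
    """Raised when a transcript fails the relatedness floor against its gene."""


class NoStartCodonError(ValueError):
    """Raised when no initiator ATG can be located in the effective mRNA."""


# ---------------------------------------------------------------------------
# gene model


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron architecture of a gene; the coordinate authority for all
    splice logic.  Introns are always derived as the gaps between consecutive
    exons, never supplied."""

    gene: SequenceRecord
    cds_start: int
    exons: tuple[GenomicInterval, ...]

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            out.append(
                GenomicInterval(self.gene.id, left.end + 1, right.start - 1)
            )
        return tuple(out)

    def exon_seq(self, i: int) -> str:
        iv = self.exons[i - 1]
        return self.gene.residues[iv.start - 1: iv.end]

    def intron_seq(self, i: int) -> str:
        iv = self.introns[i - 1]
        return self.gene.residues[iv.start - 1: iv.end]

    def coding_positions(self) -> list[int]:
        """Gene positions belonging to the CDS (cds_start to end of last exon)."""
        out = []
        for ex in self.exons:
            for p in range(ex.start, ex.end + 1):
                if p >= self.cds_start:
                    out.append(p)
        return out


def build_gene_model(
    gene: SequenceRecord,
    exons: Sequence[GenomicInterval | tuple[int, int]],
    cds_start: int,
) -> GeneModel:
    """Validate exon intervals and derive the intron structure."""
    if gene.alphabet != "nucleotide":
        raise GeneModelError("gene record must be a nucleotide sequence")
    ivs = tuple(
        e if isinstance(e, GenomicInterval)
        else GenomicInterval(gene.id, e[0], e[1])
        for e in exons
    )
    if not ivs:
        raise GeneModelError("a gene model needs at least one exon")
    for iv in ivs:
        if iv.end > len(gene):
            raise GeneModelError(f"exon {iv} outside gene of length {len(gene)}")
    for left, right in zip(ivs, ivs[1:]):
        if right.start <= left.end:
            raise GeneModelError(
                f"exons {left} and {right} overlap or are unsorted"
            )
        if right.start == left.end + 1:
            raise GeneModelError(
                f"exons {left} and {right} are adjacent; no intron between them"
            )
    first = ivs[0]
    if not (first.start <= cds_start <= first.end):
        raise GeneModelError(
            f"cds_start {cds_start} must fall within exon 1 ({first})"
        )
    return GeneModel(gene=gene, cds_start=cds_start, exons=ivs)


def intron_phase(model: GeneModel, intron_index: int) -> int:
    """Phase of intron ``intron_index`` (1-based): coding nucleotides strictly
    upstream of the intron, modulo 3."""
    introns = model.introns
    if not 1 <= intron_index <= len(introns):
        raise GeneModelError(f"no intron {intron_index} in this model")
    intron = introns[intron_index - 1]
    if intron.end < model.cds_start:
        raise GeneModelError(
            f"intron {intron_index} lies upstream of the CDS start"
        )
    upstream = 0
    for ex in model.exons:
        if ex.end < intron.start:
            upstream += max(0, ex.end - max(ex.start, model.cds_start) + 1)
    return upstream % 3


def reference_protein(model: GeneModel) -> TranslationResult:
    """Translation of the fully spliced CDS (concatenated coding exons)."""
    cds = "".join(
        model.gene.residues[p - 1] for p in model.coding_positions()
    )
    return translate_cds(cds, "arrest")


# ---------------------------------------------------------------------------
# per-feature results


@dataclass(frozen=True)
class IntronStatus:
    index: int
    status: str
    phase: int
    junction_shift: int = 0
    #: transcript coordinates flanking the splice point, in the coordinates of
    #: the transcript as supplied (antisense transcripts keep their own frame
    #: of reference); None unless the intron is spliced.
    junction_transcript: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.status not in INTRON_STATUSES:
            raise ValueError(f"bad intron status {self.status!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError("phase must be 0, 1 or 2")


@dataclass(frozen=True)
class IndelEvent:
    region: GenomicInterval
    kind: str  # deletion | insertion
    length: int

    @property
    def frame_class(self) -> str:
        return "in_frame" if self.length % 3 == 0 else "frameshift"

    @property
    def codons_affected(self) -> Optional[int]:
        return self.length // 3 if self.length % 3 == 0 else None


@dataclass(frozen=True)
class StopScan:
    intron_index: int
    frame_mode: str
    stop_triplets: tuple[int, ...]
    stop_codons: tuple[str, ...]


@dataclass(frozen=True)
class ProteinPrediction:
    product: str
    clazz: str
    missing_n_terminal: int = 0
    internal_deletions: tuple[int, ...] = ()
    arrest_codon: Optional[int] = None

    def __post_init__(self) -> None:
        if self.clazz not in PRODUCT_CLASSES:
            raise ValueError(f"bad product class {self.clazz!r}")
        if "*" in self.product:
            raise ValueError("product must not contain '*'")
        if self.clazz == "n_truncated" and self.missing_n_terminal <= 0:
            raise ValueError("n_truncated requires missing_n_terminal > 0")


@dataclass
class SpliceReport:
    gene_id: str
    transcript_id: str
    orientation: str  # strand of the transcript relative to the gene model
    identity: float
    intron_statuses: list[IntronStatus]
    indels: list[IndelEvent]
    five_prime_missing: int
    three_prime_missing: int
    aligned_gene_start: int
    aligned_gene_end: int
    prediction: Optional[ProteinPrediction] = None

    def status_of(self, intron_index: int) -> str:
        return self.intron_statuses[intron_index - 1].status

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        """Flat table: one row per intron status and per indel event."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["gene_id", "transcript_id", "record", "index",
                        "detail", "value"])
            base = [self.gene_id, self.transcript_id]
            for st in self.intron_statuses:
                w.writerow(base + ["intron", st.index, st.status,
                                   f"phase={st.phase}"])
            for ev in self.indels:
                w.writerow(base + [ev.kind, str(ev.region), ev.frame_class,
                                   f"length={ev.length}"])
            w.writerow(base + ["five_prime_missing", "", "",
                               self.five_prime_missing])
            w.writerow(base + ["three_prime_missing", "", "",
                               self.three_prime_missing])
            if self.prediction is not None:
                w.writerow(base + ["product_class", "", self.prediction.clazz,
                                   f"length={len(self.prediction.product)}"])


# ---------------------------------------------------------------------------
# stop-codon scanning


def scan_intron_stops(model: GeneModel, intron_index: int,
                      frame_mode: str = "intron_start") -> StopScan:
    """Partition an intron into consecutive triplets and report stop codons.

    ``intron_start`` counts triplets from the first intron nucleotide (the
    convention under which the MAT1-2-1 intron I stops sit at triplets 1, 3
    and 13).  ``junction_codon`` starts the first triplet with the carry-in
    nucleotides of the codon interrupted by the intron, i.e. the frame a
    ribosome would actually read through a retained intron.
    """
    from .seqcore import STOP_CODONS

    if frame_mode not in ("intron_start", "junction_codon"):
        raise ValueError(f"unknown frame mode {frame_mode!r}")
    intron = model.intron_seq(intron_index)
    if frame_mode == "junction_codon":
        # a phase-p intron interrupts a codon whose first p nucleotides sit in
        # the upstream exon; the first scanned triplet spans the junction
        phase = intron_phase(model, intron_index)
        if phase:
            iv = model.introns[intron_index - 1]
            upstream = model.gene.residues[iv.start - 1 - phase: iv.start - 1]
            scan_seq = upstream + intron
        else:
            scan_seq = intron
    else:
        scan_seq = intron
    ordinals, codons = [], []
    for i in range(len(scan_seq) // 3):
        triplet = scan_seq[3 * i: 3 * i + 3]
        if triplet in STOP_CODONS:
            ordinals.append(i + 1)
            codons.append(triplet)
    return StopScan(
        intron_index=intron_index,
        frame_mode=frame_mode,
        stop_triplets=tuple(ordinals),
        stop_codons=tuple(codons),
    )


# ---------------------------------------------------------------------------
# transcript classification


@dataclass(frozen=True)
class SpliceParams:
    """Thresholds for splice-status calls.

    Defaults are chosen so single-base sequencing errors at junctions cannot
    flip a call: an intron is spliced/retained when at least 90% of its
    positions align to gaps/residues, junction wobble of up to 2 nt is folded
    into ``junction_shift``, and alignment gaps shorter than 3 nt are treated
    as noise rather than indel events.
    """

    identity_floor: float = 80.0
    coverage_floor: float = 0.5
    splice_threshold: float = 0.9
    retention_threshold: float = 0.9
    junction_tolerance: int = 2
    min_indel: int = 3


def _orient_and_align(model: GeneModel, transcript: SequenceRecord,
                      params: SpliceParams):
    """Semiglobal-align the transcript in both orientations; keep the better."""
    ap = AlignmentParams.nucleotide("semiglobal")
    fwd = pairwise_align(model.gene.residues, transcript.residues, ap)
    rev = pairwise_align(
        model.gene.residues, reverse_complement(transcript.residues), ap
    )
    if rev.score > fwd.score:
        return rev, ANTISENSE
    return fwd, SENSE


#: largest sideways displacement of a spliced-intron gap that is snapped back
#: onto the annotated junction (co-optimal gap placements slide when the
#: intron boundary sequence coincides with its exon flank)
SLIDE_MAX = 20


def _snap_intron_gaps(gene_to_t: list[int], model: GeneModel,
                      params: "SpliceParams") -> None:
    """Canonicalise gap placement around annotated introns, in place.

    When a maximal gap run has exactly the length of an annotated intron but
    sits shifted by k positions (|k| <= SLIDE_MAX), the alignment is one of
    several co-optimal placements of the same splice; the run is moved onto
    the annotation and the displaced exon positions regain their transcript
    mapping.  Runs of any other length are left untouched — a genuine
    junction-adjacent deletion changes the run length and survives.
    """
    gene_len = len(gene_to_t) - 1
    for intron in model.introns:
        s, e = intron.start, intron.end
        mid = (s + e) // 2
        if gene_to_t[mid]:
            continue  # intron centre aligned: retained or unrelated
        a = mid
        while a > 1 and not gene_to_t[a - 1]:
            a -= 1
        b = mid
        while b < gene_len and not gene_to_t[b + 1]:
            b += 1
        if (b - a) != (e - s) or (a, b) == (s, e):
            continue
        k = a - s
        if abs(k) > SLIDE_MAX:
            continue
        if k < 0:
            # left shift: exon positions [a, s-1] take the transcript residues
            # currently mapped to the intron tail [b+1, e]
            for j in range(-k):
                gene_to_t[a + j] = gene_to_t[b + 1 + j]
                gene_to_t[b + 1 + j] = 0
        else:
            # right shift: exon positions [e+1, b] take the residues mapped to
            # the intron head [s, a-1]
            for j in range(k):
                gene_to_t[e + 1 + j] = gene_to_t[s + j]
                gene_to_t[s + j] = 0


def classify_introns(model: GeneModel, transcript: SequenceRecord,
                     params: Optional[SpliceParams] = None,
                     predict: bool = True) -> SpliceReport:
    """Classify every annotated intron of ``model`` against ``transcript``.

    Returns a :class:`SpliceReport`; with ``predict=True`` (default) the
    report also carries the predicted protein product.
    """
    params = params or SpliceParams()
    res, orientation = _orient_and_align(model, transcript, params)
    # relatedness is judged on residue-paired columns only: splicing itself
    # creates large legitimate gap columns that must not count against a
    # transcript of its own gene
    match_cols = sum(
        1 for x, y in zip(res.aligned_query, res.aligned_subject)
        if x != "-" and y != "-"
    )
    if match_cols == 0:
        raise UnrelatedTranscriptError(
            f"transcript {transcript.id!r} shares no aligned residues with "
            f"gene {model.gene.id!r}"
        )
    identity = round(100.0 * res.identities / match_cols, 1)
    tlen = len(transcript.residues)
    covered = len(res.aligned_subject.replace("-", ""))
    # aligned_subject is the oriented transcript; count its residues that fall
    # inside the trimmed alignment == subject span length
    covered = res.subject_span.end - res.subject_span.start + 1
    if identity < params.identity_floor or covered < params.coverage_floor * tlen:
        raise UnrelatedTranscriptError(
            f"transcript {transcript.id!r} does not look derived from gene "
            f"{model.gene.id!r} (identity {identity}%, coverage "
            f"{100.0 * covered / tlen:.1f}%)"
        )

    gene_len = len(model.gene)
    # gene position -> transcript position in oriented coordinates (0 = gap)
    gene_to_t = [0] * (gene_len + 1)
    insertions_after: dict[int, int] = {}
    g = t = 0
    for x, y in zip(res.aligned_query, res.aligned_subject):
        if x != "-" and y != "-":
            g += 1
            t += 1
            gene_to_t[g] = t
        elif x != "-":
            g += 1
        else:
            t += 1
            insertions_after[g] = insertions_after.get(g, 0) + 1

    _snap_intron_gaps(gene_to_t, model, params)

    aligned_positions = [p for p in range(1, gene_len + 1) if gene_to_t[p]]
    first_aln, last_aln = aligned_positions[0], aligned_positions[-1]
    five_missing = first_aln - 1
    three_missing = gene_len - last_aln

    def to_input_coords(pos: int) -> int:
        return tlen - pos + 1 if orientation == ANTISENSE else pos

    statuses: list[IntronStatus] = []
    for i, intron in enumerate(model.introns, start=1):
        phase = intron_phase(model, i)
        if intron.end < first_aln or intron.start > last_aln:
            statuses.append(IntronStatus(i, "unresolved", phase))
            continue
        positions = range(intron.start, intron.end + 1)
        n_gap = sum(1 for p in positions if not gene_to_t[p])
        n_res = len(intron) - n_gap
        junction = None
        shift = 0
        if n_gap >= params.splice_threshold * len(intron):
            status = "spliced"
            # observed 5' splice point: first gapped position of the run
            # containing the intron start
            p = intron.start
            while p > first_aln and not gene_to_t[p - 1]:
                p -= 1
            d5 = p - intron.start
            if abs(d5) <= params.junction_tolerance:
                shift = d5
            # transcript positions flanking the removed intron
            left = intron.start - 1
            while left >= 1 and not gene_to_t[left]:
                left -= 1
            right = intron.end + 1
            while right <= gene_len and not gene_to_t[right]:
                right += 1
            if left >= 1 and right <= gene_len:
                j = sorted(
                    (to_input_coords(gene_to_t[left]),
                     to_input_coords(gene_to_t[right]))
                )
                junction = (j[0], j[1])
        elif n_res >= params.retention_threshold * len(intron):
            status = "retained"
        else:
            status = "partial"
        statuses.append(
            IntronStatus(i, status, phase, junction_shift=shift,
                         junction_transcript=junction)
        )

    spliced_intron_pos = set()
    for st, intron in zip(statuses, model.introns):
        if st.status in ("spliced", "unresolved"):
            spliced_intron_pos.update(range(intron.start, intron.end + 1))

    exon_pos = set()
    for ex in model.exons:
        exon_pos.update(range(ex.start, ex.end + 1))

    indels: list[IndelEvent] = []
    run_start = None
    for p in range(first_aln, last_aln + 2):
        in_run = p <= last_aln and not gene_to_t[p]
        if in_run and run_start is None:
            run_start = p
        elif not in_run and run_start is not None:
            # split the gap run into exonic segments (intron parts are splice)
            seg_start = None
            for q in range(run_start, p + 1):
                is_exonic = q < p and q in exon_pos
                if is_exonic and seg_start is None:
                    seg_start = q
                elif not is_exonic and seg_start is not None:
                    seg_len = q - seg_start
                    if seg_len >= params.min_indel:
                        indels.append(IndelEvent(
                            region=GenomicInterval(model.gene.id, seg_start,
                                                   q - 1),
                            kind="deletion",
                            length=seg_len,
                        ))
                    seg_start = None
            run_start = None

    for g_after, count in sorted(insertions_after.items()):
        if count >= params.min_indel and first_aln <= g_after < last_aln:
            pos = max(g_after, 1)
            indels.append(IndelEvent(
                region=GenomicInterval(model.gene.id, pos, pos),
                kind="insertion",
                length=count,
            ))

    report = SpliceReport(
        gene_id=model.gene.id,
        transcript_id=transcript.id,
        orientation=orientation,
        identity=identity,
        intron_statuses=statuses,
        indels=indels,
        five_prime_missing=five_missing,
        three_prime_missing=three_missing,
        aligned_gene_start=first_aln,
        aligned_gene_end=last_aln,
    )
    if predict:
        report.prediction = predict_protein_product(report, model)
    return report


# ---------------------------------------------------------------------------
# protein prediction


def classify_lesions(n_truncated: bool, arrested: bool, frameshifted: bool,
                     middle_deletions: int) -> str:
    """Map a lesion set to a product class; >1 independent lesion = compound."""
    kinds = []
    if arrested:
        kinds.append("arrested")
    if n_truncated:
        kinds.append("n_truncated")
    if frameshifted:
        kinds.append("frameshifted")
    if middle_deletions:
        kinds.append("middle_truncated")
    if not kinds:
        return "full"
    if len(kinds) == 1:
        return kinds[0]
    return "compound"


def predict_protein_product(report: SpliceReport, model: GeneModel
                            ) -> ProteinPrediction:
    """Predict the translated product implied by a splice report.

    The effective mRNA is rebuilt from the gene: spliced introns and detected
    deletions are removed, retained (and partially retained) introns kept,
    and unaligned gene ends dropped.  Translation starts at the annotated CDS
    start, or at the first ATG of the effective mRNA when the 5' end of the
    CDS is missing (N-terminal truncation).
    """
    ref = reference_protein(model)

    deleted = set()
    for ev in report.indels:
        if ev.kind == "deletion":
            deleted.update(range(ev.region.start, ev.region.end + 1))

    status_by_index = {st.index: st.status for st in report.intron_statuses}
    keep_intron = {
        i: status_by_index[i] in ("retained", "partial")
        for i in range(1, len(model.introns) + 1)
    }

    origin: dict[int, tuple[str, int]] = {}
    for idx, ex in enumerate(model.exons, start=1):
        for p in range(ex.start, ex.end + 1):
            origin[p] = ("exon", idx)
    for idx, intr in enumerate(model.introns, start=1):
        for p in range(intr.start, intr.end + 1):
            origin[p] = ("intron", idx)

    effective: list[tuple[int, str]] = []  # (gene position, base)
    for p in range(model.cds_start, len(model.gene) + 1):
        if p < report.aligned_gene_start or p > report.aligned_gene_end:
            continue
        if p in deleted:
            continue
        feat = origin.get(p)
        if feat is None:
            continue  # beyond the annotated gene span
        if feat[0] == "intron" and not keep_intron[feat[1]]:
            continue
        effective.append((p, model.gene.residues[p - 1]))

    if not effective:
        raise NoStartCodonError("effective mRNA is empty")

    eff_seq = "".join(base for _, base in effective)
    cds_visible = (
        report.aligned_gene_start <= model.cds_start <= report.aligned_gene_end
        and model.cds_start not in deleted
    )
    if cds_visible:
        start_idx = next(
            i for i, (p, _) in enumerate(effective) if p == model.cds_start
        )
        n_trunc = False
    else:
        start_idx = eff_seq.find("ATG")
        if start_idx < 0:
            raise NoStartCodonError(
                f"no ATG found in the effective mRNA of {report.transcript_id!r}"
            )
        n_trunc = True

    tr = translate_cds(eff_seq[start_idx:], "arrest")
    product = tr.protein

    arrest_in_intron = False
    if tr.arrested:
        stop_lo = start_idx + 3 * (tr.stop_codon_ordinal - 1)
        stop_positions = [effective[i][0] for i in range(stop_lo, stop_lo + 3)]
        arrest_in_intron = any(
            origin.get(p, ("", 0))[0] == "intron" for p in stop_positions
        )

    frameshift = any(ev.frame_class == "frameshift" for ev in report.indels)
    middle = tuple(
        ev.codons_affected for ev in report.indels
        if ev.kind == "deletion" and ev.frame_class == "in_frame"
    )
    clazz = classify_lesions(n_trunc, arrest_in_intron, frameshift, len(middle))
    missing_n = len(ref.protein) - len(product) if n_trunc else 0

    return ProteinPrediction(
        product=product,
        clazz=clazz,
        missing_n_terminal=max(missing_n, 0),
        internal_deletions=middle,
        arrest_codon=tr.stop_codon_ordinal if arrest_in_intron else None,
    )


# ---------------------------------------------------------------------------
# gene model I/O


def read_gene_model_tsv(path: str | Path, gene: SequenceRecord) -> GeneModel:
    """4-column tab-separated model: gene_id, exon_start, exon_end and, on the
    first row only, cds_start."""
    exons: list[tuple[int, int]] = []
    cds_start: Optional[int] = None
    with open(path) as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 3:
                raise GeneModelError(f"short row in {path}: {row!r}")
            exons.append((int(row[1]), int(row[2])))
            if i == 0:
                if len(row) < 4:
                    raise GeneModelError("first row must carry cds_start")
                cds_start = int(row[3])
    if cds_start is None:
        raise GeneModelError(f"no rows in model file {path}")
    return build_gene_model(gene, exons, cds_start)


def write_gene_model_tsv(model: GeneModel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for i, ex in enumerate(model.exons):
            row = [model.gene.id, ex.start, ex.end]
            if i == 0:
                row.append(model.cds_start)
            w.writerow(row)


def read_gene_model_gff3(path: str | Path, gene: SequenceRecord) -> GeneModel:
    """GFF3 model: one ``gene`` feature carrying a ``cds_start`` attribute and
    its ``exon`` children."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = list(db.features_of_type("gene"))
    if not genes:
        raise GeneModelError(f"no gene feature in {path}")
    feat = genes[0]
    try:
        cds_start = int(feat.attributes["cds_start"][0])
    except (KeyError, IndexError) as exc:
        raise GeneModelError(
            "gene feature must carry a cds_start attribute"
        ) from exc
    exons = sorted(
        (f.start, f.end) for f in db.children(feat, featuretype="exon")
    )
    if not exons:
        raise GeneModelError(f"gene feature in {path} has no exon children")
    return build_gene_model(gene, exons, cds_start)


def write_gene_model_gff3(model: GeneModel, path: str | Path) -> None:
    gid = model.gene.id
    span = (model.exons[0].start, model.exons[-1].end)
    lines = ["##gff-version 3"]
    lines.append("\t".join([
        gid, "matsplice", "gene", str(span[0]), str(span[1]), ".", "+", ".",
        f"ID=gene:{gid};cds_start={model.cds_start}",
    ]))
    for i, ex in enumerate(model.exons, start=1):
        lines.append("\t".join([
            gid, "matsplice", "exon", str(ex.start), str(ex.end), ".", "+",
            ".", f"ID=exon:{gid}.{i};Parent=gene:{gid}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
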
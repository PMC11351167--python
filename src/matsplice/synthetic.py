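"""Seeded fixtures: genes, mutant transcripts and assemblies with known truth.

The generator emulates the mutation classes observed in mating-type and
pheromone-receptor transcripts of the *O. sinensis* species complex:
retained (unspliced) introns carrying stop codons, in-frame and frameshifting
exonic deletions, exonic insertions, 5'/3' transcript truncations and point
substitutions at allelic-variation rates.  Every fixture carries truth
labels computed from the construction plan, independently of the alignment
machinery that later recovers them.

Randomness comes from :class:`numpy.random.Generator` seeded with PCG64 —
a named, portable generator: a fixed seed reproduces fixtures byte for byte
on any platform.

The module also builds two deterministic stand-in gene systems
(:func:`mat121_standin`, :func:`mat111_standin`) that reproduce the published
architecture of the MAT1-2-1 and MAT1-1-1 genes for offline testing; these
are synthetic sequences, not the GenBank records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .seqcore import (
    ANTISENSE,
    SENSE,
    STOP_CODONS,
    SequenceRecord,
    reverse_complement,
    translate_cds,
)
from .splice import (
    GeneModel,
    build_gene_model,
    classify_lesions,
    reference_protein,
)

_BASES = np.array(list("ACGT"))
#: has an in-frame stop in every reading frame; planted at intron starts so
#: that any retained intron arrests translation regardless of intron phase
_ALL_FRAME_STOP_BLOCK = "GTTAAATAAATAA"

_NONSTOP_TRIPLETS = None  # filled lazily


def _nonstop_triplets() -> list[str]:
    global _NONSTOP_TRIPLETS
    if _NONSTOP_TRIPLETS is None:
        _NONSTOP_TRIPLETS = [
            a + b + c
            for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in STOP_CODONS
        ]
    return _NONSTOP_TRIPLETS


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


@dataclass(frozen=True)
class FixtureSpec:
    """Construction parameters for one synthetic gene system.

    Defaults mirror the real mating-type genes: three exons in the
    180-300 nt range, short (48-60 nt) introns, and the GC-biased base
    composition of Genotype #1 *H. sinensis* (GC ~ 0.55).
    """

    seed: int
    n_exons: int = 3
    exon_length_range: tuple[int, int] = (180, 300)
    intron_length_range: tuple[int, int] = (48, 60)
    gc_fraction: float = 0.55
    flank_length: int = 60
    substitution_rate: float = 0.0
    #: per-intron tuples of intron-start-frame triplet ordinals to seed with
    #: stop codons; None = default all-frame stop block at the intron start
    intron_stop_ordinals: Optional[tuple[Optional[tuple[int, ...]], ...]] = None

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise FixtureError("need at least one exon")
        if not 0.0 <= self.substitution_rate <= 0.2:
            raise FixtureError("substitution_rate must lie in [0, 0.2]")
        for lo, hi in (self.exon_length_range, self.intron_length_range):
            if lo < 1 or hi < lo:
                raise FixtureError("length ranges must be positive and ordered")


@dataclass(frozen=True)
class VariantPlan:
    """Mutation plan for one transcript: which introns stay unspliced, which
    exons lose or gain segments, how the ends are truncated."""

    splice_states: tuple[str, ...] = ()
    #: (exon ordinal, length, kind) with kind in {deletion, insertion}
    indels: tuple[tuple[int, int, str], ...] = ()
    truncate_5prime: int = 0
    truncate_3prime: int = 0
    substitution_rate: float = 0.0
    orientation: str = SENSE
    seed: int = 0


@dataclass(frozen=True)
class TruthLabels:
    """Ground truth attached to a generated transcript."""

    intron_statuses: tuple[str, ...]
    indels: tuple[tuple[str, int, str], ...]  # (kind, length, frame_class)
    five_prime_missing: int
    clazz: str
    product: str
    arrest_codon: Optional[int]


@dataclass(frozen=True)
class MutantTranscript:
    record: SequenceRecord
    plan: VariantPlan
    truth: TruthLabels


@dataclass
class Fixture:
    spec: FixtureSpec
    gene: SequenceRecord
    model: GeneModel
    reference_transcript: SequenceRecord
    reference_protein: str


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _random_nonstop_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    out = []
    while len(out) < n:
        codon = _random_bases(rng, 3, gc)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _controlled_intron(rng: np.random.Generator, length: int,
                       stop_ordinals: Sequence[int], gc: float) -> str:
    """Intron whose intron-start-frame triplets carry stops exactly at the
    requested ordinals."""
    n_triplets = length // 3
    if stop_ordinals and max(stop_ordinals) > n_triplets:
        raise FixtureError(
            f"stop ordinal {max(stop_ordinals)} beyond intron of "
            f"{n_triplets} triplets"
        )
    triplets = []
    nonstop = _nonstop_triplets()
    for t in range(1, n_triplets + 1):
        if t in stop_ordinals:
            triplets.append("TAA" if t % 2 else "TGA")
        else:
            triplets.append(nonstop[rng.integers(len(nonstop))])
    tail = _random_bases(rng, length - 3 * n_triplets, gc)
    return "".join(triplets) + tail


def _default_intron(rng: np.random.Generator, length: int, gc: float) -> str:
    block = _ALL_FRAME_STOP_BLOCK
    if length < len(block) + 2:
        raise FixtureError(f"intron length {length} too short")
    filler = _random_bases(rng, length - len(block) - 2, gc)
    return block + filler + "AG"


def make_gene_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministically build a gene, its model and its reference products.

    The gene starts with ATG at ``cds_start``, carries no in-frame stop in
    its coding exons, ends its CDS with a stop codon, and its introns are
    seeded with stop triplets (all-frame block by default, or at the
    requested intron-start ordinals).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.exon_length_range
    exon_lens = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_exons)]
    total = sum(exon_lens)
    exon_lens[-1] -= total % 3
    if exon_lens[-1] < 3:
        raise FixtureError("last exon too short after frame adjustment")
    n_codons = sum(exon_lens) // 3
    coding = (
        "ATG"
        + _random_nonstop_codons(rng, n_codons - 2, spec.gc_fraction)
        + ("TAA", "TGA", "TAG")[rng.integers(3)]
    )

    ilo, ihi = spec.intron_length_range
    introns = []
    for i in range(spec.n_exons - 1):
        length = int(rng.integers(ilo, ihi + 1))
        ordinals = None
        if spec.intron_stop_ordinals is not None:
            ordinals = spec.intron_stop_ordinals[i]
        if ordinals is None:
            introns.append(_default_intron(rng, length, spec.gc_fraction))
        else:
            introns.append(
                _controlled_intron(rng, length, ordinals, spec.gc_fraction)
            )

    flank5 = _random_bases(rng, spec.flank_length, spec.gc_fraction)
    flank3 = _random_bases(rng, spec.flank_length, spec.gc_fraction)

    pieces = [flank5]
    exon_ivs = []
    pos = len(flank5)
    offset = 0
    for i, elen in enumerate(exon_lens):
        pieces.append(coding[offset:offset + elen])
        exon_ivs.append((pos + 1, pos + elen))
        pos += elen
        offset += elen
        if i < len(introns):
            pieces.append(introns[i])
            pos += len(introns[i])
    pieces.append(flank3)

    gene_seq = "".join(pieces)
    gene = SequenceRecord(
        id=f"synthetic_gene_{spec.seed}", residues=gene_seq,
        description="synthetic fixture gene", alphabet="nucleotide",
    )
    model = build_gene_model(gene, exon_ivs, cds_start=spec.flank_length + 1)
    ref_tr = SequenceRecord(
        id=f"{gene.id}_mRNA", residues=coding, alphabet="nucleotide"
    )
    return Fixture(
        spec=spec, gene=gene, model=model,
        reference_transcript=ref_tr,
        reference_protein=reference_protein(model).protein,
    )


# ---------------------------------------------------------------------------
# transcript variants


def _validate_plan(fix: Fixture, plan: VariantPlan) -> None:
    model = fix.model
    n_introns = len(model.introns)
    if plan.splice_states and len(plan.splice_states) != n_introns:
        raise FixtureError(
            f"plan names {len(plan.splice_states)} splice states for "
            f"{n_introns} introns"
        )
    for state in plan.splice_states:
        if state not in ("spliced", "retained"):
            raise FixtureError(f"unknown splice state {state!r}")
    seen_exons = set()
    margin = 15
    for ordinal, length, kind in plan.indels:
        if not 1 <= ordinal <= len(model.exons):
            raise FixtureError(f"no exon {ordinal}")
        if kind not in ("deletion", "insertion"):
            raise FixtureError(f"unknown indel kind {kind!r}")
        if ordinal in seen_exons:
            raise FixtureError("overlapping planned events in one exon")
        seen_exons.add(ordinal)
        exon_len = len(model.exons[ordinal - 1])
        if kind == "deletion" and length + 2 * margin > exon_len:
            raise FixtureError(
                f"exon {ordinal} ({exon_len} nt) too short for a "
                f"{length}-nt deletion"
            )


def make_transcript_variant(fix: Fixture, plan: VariantPlan,
                            transcript_id: Optional[str] = None
                            ) -> MutantTranscript:
    """Apply a mutation plan and derive truth labels from the construction.

    Events are applied in a fixed order: intron retention, exonic indels,
    end truncations, substitutions.  Truth labels are computed from the plan
    and from direct translation of the constructed transcript (per-base
    origin tags decide whether the arresting stop lies in a retained
    intron) — no alignment is involved.
    """
    _validate_plan(fix, plan)
    model = fix.model
    rng = np.random.default_rng((plan.seed, fix.spec.seed))
    states = plan.splice_states or tuple("spliced" for _ in model.introns)

    deletions: dict[int, tuple[int, int]] = {}
    insertions: dict[int, tuple[int, str]] = {}
    coding_before = 0
    coding_starts = {}
    for idx, ex in enumerate(model.exons, start=1):
        coding_starts[idx] = coding_before
        coding_before += max(0, ex.end - max(ex.start, model.cds_start) + 1)

    for ordinal, length, kind in plan.indels:
        ex = model.exons[ordinal - 1]
        if kind == "deletion":
            start = ex.start + (len(ex) - length) // 2
            if length % 3 == 0:
                # published in-frame deletions remove whole codons; snap the
                # start onto a codon boundary so the product simply loses
                # length/3 residues
                offset = coding_starts[ordinal] + (
                    start - max(ex.start, model.cds_start)
                )
                start -= offset % 3
            deletions[ordinal] = (start, start + length - 1)
        else:
            at = ex.start + len(ex) // 2
            insertions[ordinal] = (at, _random_bases(rng, length,
                                                     fix.spec.gc_fraction))

    # transcript as (gene_pos, base, origin); inserted bases have gene_pos 0
    entries: list[tuple[int, str, tuple[str, int]]] = []
    gene_seq = model.gene.residues
    for idx, ex in enumerate(model.exons, start=1):
        dele = deletions.get(idx)
        ins = insertions.get(idx)
        for p in range(ex.start, ex.end + 1):
            if dele and dele[0] <= p <= dele[1]:
                continue
            entries.append((p, gene_seq[p - 1], ("exon", idx)))
            if ins and p == ins[0]:
                for b in ins[1]:
                    entries.append((0, b, ("insertion", idx)))
        if idx <= len(model.introns) and states[idx - 1] == "retained":
            intr = model.introns[idx - 1]
            for p in range(intr.start, intr.end + 1):
                entries.append((p, gene_seq[p - 1], ("intron", idx)))

    if plan.truncate_5prime + plan.truncate_3prime >= len(entries):
        raise FixtureError("truncations remove the whole transcript")
    if plan.truncate_5prime:
        entries = entries[plan.truncate_5prime:]
    if plan.truncate_3prime:
        entries = entries[:-plan.truncate_3prime]

    if plan.substitution_rate > 0:
        mutated = []
        for p, base, origin in entries:
            if rng.random() < plan.substitution_rate:
                base = str(rng.choice([b for b in "ACGT" if b != base]))
            mutated.append((p, base, origin))
        entries = mutated

    truth = _truth_labels(fix, plan, states, deletions, insertions, entries)

    seq = "".join(base for _, base, _ in entries)
    if plan.orientation == ANTISENSE:
        seq = reverse_complement(seq)
    tid = transcript_id or f"{fix.gene.id}_variant_{plan.seed}"
    record = SequenceRecord(id=tid, residues=seq, alphabet="nucleotide")
    return MutantTranscript(record=record, plan=plan, truth=truth)


def _truth_labels(fix: Fixture, plan: VariantPlan, states, deletions,
                  insertions, entries) -> TruthLabels:
    model = fix.model
    remaining = {p for p, _, _ in entries if p}
    first_pos = min(remaining)
    last_pos = max(remaining)

    statuses = []
    for i, intr in enumerate(model.introns, start=1):
        planned = states[i - 1]
        if planned == "retained":
            n_left = sum(
                1 for p in range(intr.start, intr.end + 1) if p in remaining
            )
            if n_left == 0:
                statuses.append("unresolved")
            elif n_left == len(intr):
                statuses.append("retained")
            else:
                statuses.append("partial")
        else:
            if intr.end < first_pos or intr.start > last_pos:
                statuses.append("unresolved")
            else:
                statuses.append("spliced")

    indel_truth = []
    for ordinal, length, kind in plan.indels:
        if kind == "deletion":
            lo, hi = deletions[ordinal]
            visible = lo > first_pos and hi < last_pos
        else:
            visible = first_pos < insertions[ordinal][0] < last_pos
        if visible:
            frame = "in_frame" if length % 3 == 0 else "frameshift"
            indel_truth.append((kind, length, frame))

    cds_missing = model.cds_start not in remaining
    seq = "".join(base for _, base, _ in entries)
    if cds_missing:
        start_idx = seq.find("ATG")
        if start_idx < 0:
            raise FixtureError("variant has no start codon left")
    else:
        start_idx = next(
            i for i, (p, _, _) in enumerate(entries) if p == model.cds_start
        )
    tr = translate_cds(seq[start_idx:], "arrest")
    arrest_in_intron = False
    if tr.arrested:
        lo = start_idx + 3 * (tr.stop_codon_ordinal - 1)
        origins = [entries[i][2][0] for i in range(lo, lo + 3)]
        arrest_in_intron = "intron" in origins

    frameshift = any(f == "frameshift" for _, _, f in indel_truth)
    middle = sum(
        1 for kind, _, f in indel_truth if kind == "deletion" and f == "in_frame"
    )
    clazz = classify_lesions(cds_missing, arrest_in_intron, frameshift, middle)
    return TruthLabels(
        intron_statuses=tuple(statuses),
        indels=tuple(indel_truth),
        five_prime_missing=first_pos - 1,
        clazz=clazz,
        product=tr.protein,
        arrest_codon=tr.stop_codon_ordinal if arrest_in_intron else None,
    )


# ---------------------------------------------------------------------------
# assemblies


def make_assembly_fixture(fix: Fixture, embed: bool, decoy_length: int,
                          seed: int, n_records: int = 3,
                          strand: Optional[str] = None,
                          ) -> tuple[list[SequenceRecord], dict]:
    """Decoy assembly records, optionally embedding the fixture gene.

    When not embedding, the decoy is verified to share no anchor k-mer with
    the gene (regenerated up to 10 times before giving up).
    """
    from .occurrence import shares_kmer

    gene_seq = fix.gene.residues
    if embed and decoy_length < len(gene_seq):
        raise FixtureError("decoy_length must be at least the gene length")
    rng = np.random.default_rng((seed, fix.spec.seed))
    per_record = max(decoy_length // n_records, 50)

    for attempt in range(10):
        records = [
            SequenceRecord(
                id=f"contig_{i + 1}",
                residues=_random_bases(rng, per_record, fix.spec.gc_fraction),
                alphabet="nucleotide",
            )
            for i in range(n_records)
        ]
        if embed:
            target = int(rng.integers(n_records))
            chosen = strand or (SENSE, ANTISENSE)[rng.integers(2)]
            insert = gene_seq if chosen == SENSE else reverse_complement(gene_seq)
            host = records[target].residues
            at = int(rng.integers(0, len(host) + 1))
            records[target] = SequenceRecord(
                id=records[target].id,
                residues=host[:at] + insert + host[at:],
                alphabet="nucleotide",
            )
            truth = {
                "embedded": True,
                "record": records[target].id,
                "position": at + 1,
                "strand": chosen,
            }
            return records, truth
        if not any(shares_kmer(gene_seq, r.residues) for r in records):
            return records, {"embedded": False}
    raise FixtureError("could not build a k-mer-free decoy in 10 attempts")


# ---------------------------------------------------------------------------
# deterministic stand-ins for the published gene systems (synthetic!)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    """One codon per residue, avoiding stop codons (synthetic helper)."""
    from Bio.Data.CodonTable import standard_dna_table

    by_aa: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    out = []
    for aa in protein:
        codons = sorted(by_aa[aa])
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def mat121_protein_standin() -> str:
    """Synthetic 249-aa protein with the four-class composition documented
    for the MAT1-2-1 protein AFX66389: 25 acidic and 41 basic residues
    (10.0% and 16.5% of 249).  Not the GenBank sequence."""
    rng = np.random.default_rng(20240632)
    pool = (
        "D" * 13 + "E" * 12                      # acidic 25
        + "K" * 20 + "R" * 15 + "H" * 6          # basic 41
        + "A" * 30 + "L" * 30 + "V" * 20 + "F" * 10 + "M" * 12  # hydrophobic
        + "S" * 25 + "T" * 20 + "G" * 20 + "N" * 15             # neutral 80
    )
    letters = list(pool)
    rng.shuffle(letters)
    protein = "M" + "".join(letters)
    assert len(protein) == 249
    return protein


def mat121_standin() -> tuple[Fixture, dict]:
    """Synthetic stand-in for the MAT1-2-1 gene JQ325153 (not the accession).

    Reproduces the published architecture: intron I at 187→238 (52 nt,
    phase 2) carrying stop triplets at intron-start ordinals 1, 3 and 13
    (and a phase-2-frame stop for translational arrest), intron II at
    535→589 (55 nt, phase 1), and a 249-aa protein product.
    """
    rng = np.random.default_rng(20240633)
    protein = mat121_protein_standin()
    coding = _back_translate(protein, rng) + "TGA"  # 750 nt
    cds_start = 98
    exon1_len = 186 - cds_start + 1       # 89 nt -> intron I phase 2
    exon2_len = 534 - 239 + 1             # 296 nt -> intron II phase 1
    exon3_len = 750 - exon1_len - exon2_len

    nonstop = _nonstop_triplets()

    def filler_triplet() -> str:
        return nonstop[rng.integers(len(nonstop))]

    # intron I: 52 nt = 17 triplets + 1 nt; stops at ordinals 1, 3, 13 in the
    # intron-start frame; triplets 4/5 chosen so the phase-2 ribosome frame
    # (intron offsets 11-13) reads TAA and arrests translation
    triplets = []
    for t in range(1, 18):
        if t == 1:
            triplets.append("TAA")
        elif t == 3:
            triplets.append("TGA")
        elif t == 13:
            triplets.append("TAA")
        elif t == 2:
            triplets.append("CAT")
        elif t == 4:
            triplets.append("CTA")
        elif t == 5:
            triplets.append("ACC")
        else:
            triplets.append(filler_triplet())
    intron1 = "".join(triplets) + "C"
    assert len(intron1) == 52

    intron2 = "GT" + _controlled_intron(rng, 51, (), 0.55) + "AG"
    assert len(intron2) == 55

    flank5 = _random_bases(rng, cds_start - 1, 0.55)
    flank3 = _random_bases(rng, 60, 0.55)
    gene_seq = (
        flank5
        + coding[:exon1_len]
        + intron1
        + coding[exon1_len:exon1_len + exon2_len]
        + intron2
        + coding[exon1_len + exon2_len:]
        + flank3
    )
    gene = SequenceRecord(
        id="synthetic_JQ325153_like", residues=gene_seq,
        description="synthetic stand-in gene (MAT1-2-1 architecture)",
        alphabet="nucleotide",
    )
    exons = [
        (cds_start, 186),
        (239, 534),
        (590, 589 + exon3_len),
    ]
    model = build_gene_model(gene, exons, cds_start=cds_start)
    spec = FixtureSpec(seed=20240633)
    fix = Fixture(
        spec=spec, gene=gene, model=model,
        reference_transcript=SequenceRecord(
            id=f"{gene.id}_mRNA", residues=coding, alphabet="nucleotide"
        ),
        reference_protein=reference_protein(model).protein,
    )
    info = {
        "intron1": (187, 238),
        "intron2": (535, 589),
        "stop_ordinals": (1, 3, 13),
        "protein_length": len(protein),
    }
    return fix, info


def mat111_standin() -> tuple[Fixture, dict]:
    """Synthetic stand-in for the MAT1-1-1 gene (KC437356 region architecture;
    not the accession).

    CDS of 1119 bp (372 aa + stop TAG) over three exons of 238 / 819 / 62
    coding nt, a 52-nt intron I and a 48-nt intron II.  Codon 97 is ATG so
    that the 5'-truncated metatranscript restarts there, and codons 150-167
    encode the published 18-aa segment deleted in the middle-truncated
    variant.
    """
    from .published import OSIN7648_DELETED_SEGMENT

    rng = np.random.default_rng(20240634)
    protein = list("M" + "".join(
        "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)] for _ in range(371)
    ))
    protein[96] = "M"  # restart methionine for the N-truncated variant
    protein[149:167] = list(OSIN7648_DELETED_SEGMENT)
    protein = "".join(protein)
    coding = _back_translate(protein, rng) + "TAG"
    assert len(coding) == 1119

    flank = 50
    exon_lens = (238, 819, 62)
    intron1 = _default_intron(rng, 52, 0.55)
    intron2 = _default_intron(rng, 48, 0.55)
    gene_seq = (
        _random_bases(rng, flank, 0.55)
        + coding[:238] + intron1
        + coding[238:1057] + intron2
        + coding[1057:]
        + _random_bases(rng, flank, 0.55)
    )
    gene = SequenceRecord(
        id="synthetic_KC437356_like", residues=gene_seq,
        description="synthetic stand-in gene (MAT1-1-1 architecture)",
        alphabet="nucleotide",
    )
    e1 = (flank + 1, flank + 238)
    i1_end = e1[1] + 52
    e2 = (i1_end + 1, i1_end + 819)
    i2_end = e2[1] + 48
    e3 = (i2_end + 1, i2_end + 62)
    model = build_gene_model(gene, [e1, e2, e3], cds_start=flank + 1)
    fix = Fixture(
        spec=FixtureSpec(seed=20240634), gene=gene, model=model,
        reference_transcript=SequenceRecord(
            id=f"{gene.id}_mRNA", residues=coding, alphabet="nucleotide"
        ),
        reference_protein=reference_protein(model).protein,
    )
    info = {
        "protein_length": 372,
        "restart_codon": 97,
        "deleted_segment_codons": (150, 167),
    }
    return fix, info


def mat111_gagw_like_transcript() -> SequenceRecord:
    """Synthetic stand-in for the GAGW01008880 metatranscript (not the
    accession): the MAT1-1-1 stand-in mRNA missing exon I plus the first
    48 bp of exon II, followed by a 296-nt noncoding tail, deposited in the
    antisense orientation — so the spliced 48-nt intron II junction falls
    between transcript nucleotides 358 and 359 of the record as supplied.
    """
    fix, _ = mat111_standin()
    coding = fix.reference_transcript.residues
    rng = np.random.default_rng(20240635)
    sense = coding[238 + 48:] + _random_bases(rng, 296, 0.45)
    return SequenceRecord(
        id="synthetic_GAGW01008880_like",
        residues=reverse_complement(sense),
        description="synthetic stand-in metatranscript (antisense deposit)",
        alphabet="nucleotide",
    )


def mat111_osin_like_transcript() -> SequenceRecord:
    """Synthetic stand-in for the OSIN7648 metatranscript: both introns
    spliced plus the 54-bp in-frame deletion (18 codons) within exon II."""
    fix, info = mat111_standin()
    coding = fix.reference_transcript.residues
    lo = (info["deleted_segment_codons"][0] - 1) * 3
    hi = info["deleted_segment_codons"][1] * 3
    return SequenceRecord(
        id="synthetic_OSIN7648_like",
        residues=coding[:lo] + coding[hi:],
        description="synthetic stand-in metatranscript (54-bp deletion)",
        alphabet="nucleotide",
    )
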
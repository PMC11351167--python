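# Methods

This note records the models, conventions and numerical choices behind
`matsplice`, and what its synthetic-data tests do and do not demonstrate.

## Coordinates, translation, alignment

All public coordinates are 1-based inclusive with `start→end` (sense) /
`start←end` (antisense) rendering, the citation style of fungal gene
annotations; storage is 0-based half-open behind round-trip-tested
converters.  Translation uses the standard nuclear genetic code with stop
set {TAA, TGA, TAG}; ambiguity bases other than N are rejected at parse
time so data problems surface instead of being coerced.

Pairwise alignment wraps Biopython's `PairwiseAligner` in three modes
(global, semiglobal with free end gaps, local).  A gap of length L costs
`gap_open + L·gap_extend` (BLAST "existence + extension"); defaults are
nucleotide +2/−3 with gaps −5/−2 and protein BLOSUM62 with gaps −11/−1,
mirroring the BLAST-family programs these desk-scale comparisons replace.
Co-optimal alignments are resolved deterministically by taking the first
traceback in the engine's fixed exploration order; the test suite checks
scores against an independent exhaustive-search oracle (top-down recursion
over (i, j, previous-column-state)) for all sequence pairs up to length 8,
in global and semiglobal mode, nucleotide and protein scoring.  Reported
percent identity divides by aligned columns (internal gaps included, free
end gaps excluded), rounded half-up to 0.1; because published "similarity"
percentages are BLAST-dialect dependent they are treated as soft context,
not as targets.

Inputs above 5 Mb per side are refused by the exact dynamic program; the
occurrence module's anchored path (below) is the supported route for
assembly-scale subjects.

## Splice-status classification

A transcript is aligned semiglobally against its gene in both orientations
and the better-scoring orientation is kept; junction coordinates are always
reported in the coordinates of the transcript *as supplied*, so antisense
metatranscript deposits keep their own frame of reference.

Relatedness gate: the 80 % identity floor is evaluated over residue-paired
columns only, with an additional requirement that at least half the
transcript aligns.  Two reasons: (i) splicing itself creates large,
legitimate gap columns that would dilute a column-denominator identity;
(ii) an optimal semiglobal alignment of unrelated sequences can exceed any
identity floor over a tiny anchored region, so identity alone cannot reject
junk — coverage can.

Per intron, with defaults chosen so a single-base error at a junction
cannot flip a call: *spliced* if ≥ 90 % of intron positions pair with gaps,
*retained* if ≥ 90 % pair with residues, *partial* otherwise, *unresolved*
if the intron lies wholly outside the aligned gene span (e.g. inside a 5′
truncation).  Junction wobble of up to ±2 nt is recorded as
`junction_shift`.  Gap runs of 1–2 nt are always treated as
wobble/sequencing noise (the minimum reportable indel is 3 nt); the
alternative of confirming 1–2 nt frameshifts over a downstream window was
considered and not implemented, as no event class in scope requires it.

Gap-placement canonicalisation: when flanking sequence coincides, affine-gap
alignment may slide a spliced intron's gap run sideways, manufacturing a
phantom junction-adjacent "deletion" plus an equally long stretch of intron
positions aligned to residues.  Any maximal gap run of exactly intron length
displaced by ≤ 20 nt from an annotated intron is therefore snapped onto the
annotation and the displaced exon positions regain their transcript
mapping.  A genuine junction-adjacent deletion changes the run length and
survives untouched.

## Protein prediction

The effective mRNA is rebuilt from the *gene*: spliced (and unresolved)
introns and detected deletions removed, retained/partial introns kept,
unaligned gene ends dropped.  Translation starts at the annotated CDS
start; if the 5′ CDS is missing or deleted, at the first ATG of the
effective mRNA (class `n_truncated`, `missing_n_terminal` = reference
length − product length, matching how truncated products are reported for
real metatranscripts; a floor(missing nt/3) estimate disagrees with the
ATG-restart product by one residue whenever the truncation is not
codon-aligned).  An in-frame stop whose codon overlaps a retained intron is
a translational-arrest lesion; any indel of length ≢ 0 (mod 3) is a
frameshift lesion; in-frame deletions are middle-truncation lesions.  One
lesion gives its own class; two or more independent lesions give
`compound`.  A 3′ truncation of coding sequence shortens the product but is
not an extra lesion class of its own.

Stop-codon scanning of introns offers two frames, reported side by side
because published triplet counts ("the first … triplet" of an intron) are
ambiguous about the frame: `intron_start` partitions from the intron's
first base (the counting that places the MAT1-2-1 intron I stops at
triplets 1, 3, 13); `junction_codon` starts with the `phase` carry-in
nucleotides of the interrupted codon — the frame a ribosome actually reads
through a retained intron.

## Composition and propensity profiles

The default residue scheme ("peptide2-like") is acidic {D,E}, basic
{H,K,R}, hydrophobic {A,C,F,I,L,M,P,V,W}, neutral {G,N,Q,S,T,Y}.  Acidic
and basic membership is uncontroversial and reproduces the verifiable
published table cells; the hydrophobic/neutral assignment of C, G, P, Y is
a convention of the web tool being emulated and is therefore a pluggable
two-column data file (hydrophobic-class cells are treated as soft checks —
published 41.2 % of a 249-aa protein corresponds to no integer count).
Counts are exact integers; rounding (half-up, one decimal) happens only at
report time.

Propensity profiles slide an odd window (default 21) over the protein under
the linear weight variation model: relative weights interpolate linearly
from `edge_weight` at the extremities to 1.0 at the centre, then normalise
to sum one.  `edge_weight` defaults to 1.0 (uniform — the common ProtScale
default); the weighting family, not a specific edge value, is what the
model name selects, so it is a first-class parameter.  Default scales are
the Deléage & Roux (1987) conformational parameters — the one family
offering all four of helix, sheet, turn and coil — with Chou–Fasman
helix/sheet/turn as alternates; all ship as two-column data files with
provenance headers.  Only full windows are scored.  No figures are
rendered; profiles export as TSV.

Waveform comparison (`compare_profiles`) works over alignment-matched
centre positions: Pearson correlation, maximum |Δ|, and contiguous runs
with |Δ| > k·σ (k default 2) as candidate variable-segment regions.  σ is
the standard deviation of the *difference signal*, not of the reference
waveform: window-21 smoothing makes the reference SD larger than the
largest difference an 18-residue deletion can produce, so a
reference-scaled threshold would miss essentially all localized divergence,
whereas the difference signal is near zero away from lesions and is the
actual comparison-noise scale.  Identical profiles give σ = 0 and no runs.
Because the exact author scales and edge weight behind published plots are
unstated, waveform claims are checked as properties (planted deletions must
be flagged near their locus), never as point values.

## Occurrence screening

Queries are anchored to subjects by exact 31-mers (both strands); each
anchored record contributes a semiglobal alignment of the query against the
seeded subject window (±200 nt margin).  Absence of any anchor k-mer is an
absence call without alignment.  Presence requires best identity ≥ 90 % and
query coverage ≥ 80 % — published presence claims involve 95–100 %
homologies, so the defaults sit safely below them while excluding spurious
hits; both are configurable.  Hits never span record boundaries; a gene
split across contigs is reported as multiple partial hits whose coverage
combines (identity then being the span-weighted mean).  Raising a threshold
can only turn presences into absences, never the reverse.

## Synthetic data: what it emulates, what it does not

The generator (NumPy PCG64; a fixed seed reproduces fixtures byte for byte)
builds three-exon genes by default with 180–300 nt exons, 48–60 nt introns
and GC fraction 0.55 — the architecture and GC bias of the real mating-type
genes.  Coding sequence is drawn codon-wise with no premature stops;
introns get canonical GT…AG ends (cosmetic; the classifier does not use
them) and are seeded at their start with a 13-nt block containing a stop in
every reading frame, so a retained intron arrests translation regardless of
phase — the behaviour observed for the real unspliced intron I.  Stop
triplets can instead be planted at requested intron-start ordinals.
Transcript variants apply retained introns, exonic indels (in-frame
deletions snapped to codon boundaries, as the published 54-bp/18-aa event
implies), end truncations and substitutions, in that order, and carry truth
labels computed from the construction plan plus direct translation of the
constructed transcript — never from alignment.  The generator and the
classifier share only the final lesion-set→class mapping, so recovery tests
validate the inference path, not the taxonomy.

Two deterministic stand-in gene systems reproduce the *published
architecture* of the MAT1-2-1 and MAT1-1-1 genes (intron coordinates
187→238/535→589 and phases 2/1; stop ordinals 1, 3, 13; CDS 1119 bp over
238/819/62 coding nt with a 52/48 nt intron pair; restart methionine at
codon 97; the published 18-aa segment at codons 150–167) because the
GenBank records themselves are not bundled.  Passing tests on stand-ins
demonstrates that the *operations* reproduce the published numbers on
sequences with the documented structure; they are not evidence about the
accession sequences themselves, and any analysis of real data should fetch
the accessions and run the same operations.

What the generator does not emulate: sequencing reads and read-level error
models, non-uniform substitution processes, trans-splicing, multi-isoform
mixtures, and assembly artefacts other than contig splits.  Recovery being
100 % on fixtures therefore bounds algorithmic correctness, not robustness
to pathological real-world assemblies.

## Problem sizes and determinism

The shipped test and acceptance runs use 200 fixtures for parameter
recovery, 100 for divergence detection, 500 sequence pairs for the
alignment oracle and 200 random models for the phase recurrence — sizes at
which every suite completes in seconds on one CPU while estimating the
rates to within a few percent.  All randomness flows from explicit seeds;
reruns are byte-identical, including CLI outputs.
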
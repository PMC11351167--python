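"""Published coordinates and printed sequence segments used as inputs.

These values come from the GenBank-accessioned records of the *Hirsutella
sinensis* / *Ophiocordyceps sinensis* mating-type and pheromone-receptor
literature.  Full accession sequences are not bundled (fetching is the
user's responsibility); what is collected here are the printed annotation
coordinates and the short sequence segments reproduced verbatim in reports,
which are sufficient for coordinate arithmetic and segment-length checks.
"""

from __future__ import annotations

from .seqcore import GenomicInterval

# --- MAT1-2-1 gene (JQ325153, H. sinensis strain GS09_121) -----------------

#: intron I, "Intron Phase-Two": 52 nt
JQ325153_INTRON_I = GenomicInterval("JQ325153", 187, 238)
#: intron II, "Intron Phase-One": 55 nt
JQ325153_INTRON_II = GenomicInterval("JQ325153", 535, 589)
#: stop-codon triplet ordinals within unspliced intron I, counted from the
#: first intron nucleotide (TAA/TGA at the first, third and 13th triplets)
JQ325153_INTRON_I_STOP_ORDINALS = (1, 3, 13)
#: the MAT1-2-1 protein (AFX66389) length in residues
MAT1_2_1_PROTEIN_LENGTH = 249
#: Table-style four-class composition counts of the 249-aa MAT1-2-1 protein
#: implied by the published acidic 10.0% and basic 16.5% cells
MAT1_2_1_ACIDIC_COUNT = 25   # 25/249 -> 10.0%
MAT1_2_1_BASIC_COUNT = 41    # 41/249 -> 16.5%

# --- MAT1-1-1 gene (KC437356 region, strain 1229; protein AGW27560) --------

#: full MAT1-1-1 protein length (AGW27560)
MAT1_1_1_PROTEIN_LENGTH = 372
#: MAT1-1-1 coding sequence length (1119 bp = 372 codons + stop)
MAT1_1_1_CDS_LENGTH = 1119
#: the 18-aa segment deleted in the OSIN7648 metatranscript (54-bp in-frame
#: deletion within exon II)
OSIN7648_DELETED_SEGMENT = "SMQREYQAPREFYDYSVS"
#: N-terminal portion printed for the truncated protein translated from
#: GAGW01008880 (reported as "96 aa shorter"; the printed string runs to 97
#: letters, an internal inconsistency of the source report — both numbers are
#: recorded, computation carries its own value)
GAGW01008880_NTERMINAL_SEGMENT = (
    "MTTRNEVMQRLSSVRADVLLNF"
    "LTDDAIFQLASRYHESTTEADVLTPVSTAAASR"
    "ATRQTKEASCDRAKRPLNAFMAFR"
    "SYYLKLFPDVQQQKTASG"
)
GAGW01008880_REPORTED_MISSING_AA = 96
GAGW01008880_PROTEIN_LENGTH = 276
#: GAGW01008880 lacks exon I (238 coding bp) and the first 48 bp of exon II;
#: its 48-bp intron II is spliced between transcript nucleotides 358 and 359
GAGW01008880_MISSING_EXON1_BP = 238
GAGW01008880_MISSING_EXON2_BP = 48
GAGW01008880_INTRON_II_LENGTH = 48
GAGW01008880_SPLICE_JUNCTION = (358, 359)

# --- a-pheromone receptor PRE-1 (KE659055, strain Co18) ---------------------

PRE1_GENE = GenomicInterval("KE659055", 3, 1386)
PRE1_INTRON_I = GenomicInterval("KE659055", 437, 490)
PRE1_INTRON_II = GenomicInterval("KE659055", 1018, 1075)

# --- alpha-pheromone receptor (KE653642, strain Co18) -----------------------

ALPHA_RECEPTOR_GENE = GenomicInterval("KE653642", 2275, 3724)
ALPHA_RECEPTOR_INTRON_I = GenomicInterval("KE653642", 3091, 3240)
ALPHA_RECEPTOR_INTRON_II = GenomicInterval("KE653642", 3528, 3586)
#: 45-aa protein segment encoded by the 133-bp exon-I deletion between the
#: LKHE01001069 / LKHE01000580 assembly segments of strain 1229.  (133 bp is
#: not a multiple of 3 while 45 aa = 135 nt; the nucleotide event and the
#: protein-level segment are reported separately and not forced to agree.)
STRAIN1229_DELETED_PROTEIN_SEGMENT = (
    "ALVVAFAVLALTPAAKLRRPSSLLHLAGLAMCLARVGSLAVPALS"
)
STRAIN1229_GENOMIC_DELETION_BP = 133
#: OSIN6424 transcript deletion in exon II: annotated as 58 bp between cDNA
#: nucleotides 885 and 886 (not a multiple of 3 -> frameshift).  The printed
#: string lost two characters in text extraction; the annotated length is
#: authoritative.
OSIN6424_DELETION_BP = 58
OSIN6424_DELETION_SEGMENT_PRINTED = (
    "GTCGTCATCATCCTCCCCCTGGGCACCCTCGCCGCCCAGCCATGACAGCCCTCC" "CA"
)
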
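"""Four-class amino-acid composition (hydrophobic / acidic / basic / neutral).

The default scheme mirrors the Peptide 2.0 hydrophobicity/hydrophilicity
classification: acidic {D, E}, basic {H, K, R}, hydrophobic
{A, C, F, I, L, M, P, V, W}, neutral {G, N, Q, S, T, Y}.  Acidic and basic
membership is uncontroversial; the hydrophobic/neutral assignment of C, G, P
and Y is a convention, so schemes are pluggable two-column data files.

Counts are exact integers; percentages are rounded half-up to one decimal at
report time only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .seqcore import SequenceRecord, round_half_up

CLASSES = ("hydrophobic", "acidic", "basic", "neutral")

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ResidueClassScheme:
    """Total mapping of the 20 standard residues onto the four classes."""

    name: str
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(_STANDARD_RESIDUES) - set(self.mapping)
        if missing:
            raise ValueError(f"scheme {self.name!r} misses residues {sorted(missing)}")
        extra = set(self.mapping) - set(_STANDARD_RESIDUES)
        if extra:
            raise ValueError(f"scheme {self.name!r} maps non-standard {sorted(extra)}")
        bad = {v for v in self.mapping.values()} - set(CLASSES)
        if bad:
            raise ValueError(f"scheme {self.name!r} uses unknown classes {sorted(bad)}")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None
                  ) -> "ResidueClassScheme":
        """Two-column text: residue <whitespace> class, '#' comments allowed."""
        mapping = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            residue, klass = line.split()
            mapping[residue.upper()] = klass.lower()
        return cls(name=name or Path(path).stem, mapping=mapping)


def default_scheme() -> ResidueClassScheme:
    path = resources.files("matsplice.data").joinpath("scheme_peptide2_like.txt")
    return ResidueClassScheme.from_file(str(path), name="peptide2-like")


@dataclass(frozen=True)
class CompositionProfile:
    protein_id: str
    scheme: str
    length: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.length:
            raise ValueError("class counts must sum to the residue count")

    def percentage(self, klass: str) -> float:
        return round_half_up(100.0 * self.counts[klass] / self.length, 1)

    @property
    def percentages(self) -> dict[str, float]:
        return {k: self.percentage(k) for k in CLASSES}


def classify_residue(aa: str, scheme: ResidueClassScheme | None = None) -> str:
    scheme = scheme or default_scheme()
    aa = aa.upper()
    if aa not in scheme.mapping:
        raise KeyError(f"residue {aa!r} is not a standard amino acid")
    return scheme.mapping[aa]


def composition_profile(protein: SequenceRecord | str,
                        scheme: ResidueClassScheme | None = None,
                        on_unknown: str = "skip") -> CompositionProfile:
    """Count and classify every residue of a protein.

    Non-standard residues (X) are skipped with a warning by default;
    ``on_unknown='error'`` makes them fatal.
    """
    scheme = scheme or default_scheme()
    if isinstance(protein, str):
        protein = SequenceRecord(id="protein", residues=protein, alphabet="protein")
    if protein.alphabet != "protein":
        raise ValueError("composition_profile requires a protein record")
    counts = {k: 0 for k in CLASSES}
    skipped = 0
    for aa in protein.residues:
        if aa in scheme.mapping:
            counts[scheme.mapping[aa]] += 1
        else:
            if on_unknown == "error":
                raise ValueError(f"non-standard residue {aa!r} in {protein.id}")
            skipped += 1
    if skipped:
        warnings.warn(
            f"{protein.id}: skipped {skipped} non-standard residue(s)",
            stacklevel=2,
        )
    length = sum(counts.values())
    if length == 0:
        raise ValueError(f"protein {protein.id!r} has no classifiable residues")
    return CompositionProfile(
        protein_id=protein.id, scheme=scheme.name, length=length, counts=counts
    )


def compare_compositions(a: CompositionProfile, b: CompositionProfile
                         ) -> dict[str, float | bool]:
    """Per-class percentage deltas (b minus a) plus a zero-delta flag."""
    if a.scheme != b.scheme:
        raise ValueError(
            f"profiles use different schemes ({a.scheme!r} vs {b.scheme!r})"
        )
    deltas = {
        k: round_half_up(b.percentage(k) - a.percentage(k), 1) for k in CLASSES
    }
    return {**deltas, "zero_delta": all(v == 0.0 for v in deltas.values())}


def profiles_to_tsv(profiles: list[CompositionProfile], path: str | Path) -> None:
    """Table in the column order of the published composition tables."""
    lines = ["protein_id\tlength\thydrophobic\tacidic\tbasic\tneutral"]
    for p in profiles:
        pct = p.percentages
        lines.append(
            f"{p.protein_id}\t{p.length}\t" +
            "\t".join(f"{pct[k]:.1f}" for k in CLASSES)
        )
    Path(path).write_text("\n".join(lines) + "\n")
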
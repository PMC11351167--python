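"""Sliding-window conformational-propensity profiles (ProtScale-style).

A 20-value amino-acid scale is slid over a protein with an odd window
(default 21) under the linear weight variation model: relative weights
interpolate linearly from ``edge_weight`` at both window extremities to 1.0
at the centre and are then normalised to sum to one.  ``edge_weight = 1.0``
(the ProtScale default) gives a plain moving average.

Profiles for the four conformational states (alpha-helix, beta-sheet,
beta-turn, coil) use the Deleage & Roux (1987) conformational parameters by
default — the one scale family providing all four named curves — with the
Chou-Fasman helix/sheet/turn propensities available as alternates.

``compare_profiles`` quantifies mutant-vs-reference waveform change over
alignment-matched positions: Pearson correlation, maximum absolute
difference, and contiguous runs where the difference exceeds k standard
deviations of the reference profile (candidate variable segment regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from .alignment import AlignmentResult
from .seqcore import SequenceRecord

DEFAULT_WINDOW = 21

_DEFAULT_SCALES = {
    "helix": "scale_deleage_roux_helix.txt",
    "sheet": "scale_deleage_roux_sheet.txt",
    "turn": "scale_deleage_roux_turn.txt",
    "coil": "scale_deleage_roux_coil.txt",
}
_ALTERNATE_SCALES = {
    "chou_fasman_helix": "scale_chou_fasman_helix.txt",
    "chou_fasman_sheet": "scale_chou_fasman_sheet.txt",
    "chou_fasman_turn": "scale_chou_fasman_turn.txt",
}


@dataclass(frozen=True)
class ScaleTable:
    """20 per-residue propensity values with a literature provenance tag."""

    name: str
    values: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(
                f"scale {self.name!r} must map exactly 20 residues, "
                f"got {len(self.values)}"
            )
        for aa, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"scale {self.name!r}: value for {aa} not finite")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "ScaleTable":
        """Two-column text: residue <whitespace> value; '#' comment lines."""
        values: dict[str, float] = {}
        provenance = ""
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line.startswith("#"):
                provenance = provenance or line.lstrip("# ")
                continue
            if not line:
                continue
            aa, val = line.split()
            values[aa.upper()] = float(val)
        return cls(name=name or Path(path).stem, values=values,
                   provenance=provenance)


def load_scale(name: str) -> ScaleTable:
    """Load a bundled scale: helix/sheet/turn/coil or chou_fasman_*."""
    try:
        filename = {**_DEFAULT_SCALES, **_ALTERNATE_SCALES}[name]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; bundled scales: "
            f"{sorted({**_DEFAULT_SCALES, **_ALTERNATE_SCALES})}"
        ) from None
    path = resources.files("matsplice.data").joinpath(filename)
    return ScaleTable.from_file(str(path), name=name)


@dataclass(frozen=True)
class WeightVector:
    """Symmetric window weights, linearly varying edge -> centre, sum 1."""

    window: int
    edge_weight: float
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must be normalised to sum 1")
        if self.weights != tuple(reversed(self.weights)):
            raise ValueError("weights must be symmetric")


def window_weights(window: int = DEFAULT_WINDOW, edge_weight: float = 1.0
                   ) -> WeightVector:
    """Linear weight variation: relative weight ``edge_weight`` at the two
    extremities rising linearly to 1.0 at the centre, then normalised."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if not 0.0 < edge_weight <= 1.0:
        raise ValueError("edge_weight must be in (0, 1]")
    centre = window // 2
    if centre == 0:
        rel = np.array([1.0])
    else:
        rel = edge_weight + (1.0 - edge_weight) * (
            1.0 - np.abs(np.arange(window) - centre) / centre
        )
    weights = rel / rel.sum()
    return WeightVector(window=window, edge_weight=edge_weight,
                        weights=tuple(float(w) for w in weights))


@dataclass(frozen=True)
class ScaleProfile:
    """Windowed scores indexed by the 1-based centre residue position."""

    protein_id: str
    scale: str
    positions: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.scores):
            raise ValueError("positions and scores must align")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.positions), np.asarray(self.scores)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["position\tscore"]
        lines += [f"{p}\t{s:.6f}" for p, s in zip(self.positions, self.scores)]
        Path(path).write_text("\n".join(lines) + "\n")


def windowed_profile(protein: SequenceRecord | str, scale: ScaleTable,
                     weights: Optional[WeightVector] = None) -> ScaleProfile:
    """Weighted sliding-window profile; only full windows are scored, so the
    centre positions run from (window-1)/2 + 1 to length - (window-1)/2."""
    weights = weights or window_weights()
    if isinstance(protein, str):
        protein = SequenceRecord(id="protein", residues=protein,
                                 alphabet="protein")
    seq = protein.residues
    w = weights.window
    if len(seq) < w:
        raise ValueError(
            f"protein {protein.id!r} ({len(seq)} aa) shorter than window {w}"
        )
    try:
        vals = np.array([scale.values[aa] for aa in seq])
    except KeyError as exc:
        raise ValueError(
            f"protein {protein.id!r} contains residue {exc} absent from scale "
            f"{scale.name!r}"
        ) from None
    kernel = np.asarray(weights.weights)
    scores = np.convolve(vals, kernel[::-1], mode="valid")
    half = (w - 1) // 2
    positions = tuple(range(half + 1, len(seq) - half + 1))
    return ScaleProfile(
        protein_id=protein.id, scale=scale.name, positions=positions,
        scores=tuple(float(s) for s in scores),
    )


@dataclass(frozen=True)
class ProfileDivergence:
    """Waveform comparison of a mutant profile against its reference."""

    scale: str
    n_positions: int
    correlation: float
    max_abs_difference: float
    #: (ref_start, ref_end) centre-position runs where |delta| exceeds the
    #: threshold — candidate variable segment regions
    divergent_runs: tuple[tuple[int, int], ...]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "n_positions": self.n_positions,
            "correlation": self.correlation,
            "max_abs_difference": self.max_abs_difference,
            "divergent_runs": [list(r) for r in self.divergent_runs],
            "threshold": self.threshold,
        }


def _matched_positions(mapping: AlignmentResult) -> list[tuple[int, int]]:
    """(ref_pos, mut_pos) pairs for alignment columns where both proteins have
    a residue."""
    pairs = []
    r = m = 0
    for x, y in zip(mapping.aligned_query, mapping.aligned_subject):
        if x != "-":
            r += 1
        if y != "-":
            m += 1
        if x != "-" and y != "-":
            pairs.append((r, m))
    return pairs


def compare_profiles(ref: ScaleProfile, mut: ScaleProfile,
                     mapping: AlignmentResult, k: float = 2.0,
                     min_run: int = 1) -> ProfileDivergence:
    """Compare two profiles over alignment-matched centre positions.

    ``mapping`` aligns the reference protein (query) to the mutant (subject).
    Runs where |mut - ref| exceeds ``k`` standard deviations of the
    difference signal are reported in reference coordinates as candidate
    variable segment regions.  (The spread of the differences, not of the
    reference waveform, is the comparison noise scale: windowed profiles are
    heavily smoothed, so localized divergence is small against the waveform
    amplitude but large against the near-zero difference background.)
    """
    if ref.scale != mut.scale:
        raise ValueError("profiles computed under different scales")
    ref_scores = dict(zip(ref.positions, ref.scores))
    mut_scores = dict(zip(mut.positions, mut.scores))
    matched = [
        (rp, mp) for rp, mp in _matched_positions(mapping)
        if rp in ref_scores and mp in mut_scores
    ]
    if not matched:
        raise ValueError("no overlapping scored positions between profiles")
    r = np.array([ref_scores[rp] for rp, _ in matched])
    m = np.array([mut_scores[mp] for _, mp in matched])
    delta = np.abs(m - r)
    if np.std(r) == 0 or np.std(m) == 0:
        corr = 1.0 if np.allclose(r, m) else 0.0
    else:
        corr = float(stats.pearsonr(r, m).statistic)
    sigma = float(np.std(delta))
    threshold = k * sigma
    runs: list[tuple[int, int]] = []
    start = None
    for (rp, _), d in zip(matched, delta):
        if d > threshold:
            if start is None:
                start = rp
            end = rp
        else:
            if start is not None and end - start + 1 >= min_run:
                runs.append((start, end))
            start = None
    if start is not None and end - start + 1 >= min_run:
        runs.append((start, end))
    return ProfileDivergence(
        scale=ref.scale,
        n_positions=len(matched),
        correlation=corr,
        max_abs_difference=float(delta.max()),
        divergent_runs=tuple(runs),
        threshold=threshold,
    )
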
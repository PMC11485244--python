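"""Sequence-level chain arithmetic: segment masses, composition, fragment
boundaries, and in-silico chymotryptic digestion.

All residue coordinates are 1-based inclusive and refer to the full-length
parent sequence (UniProt-style numbering), never to a segment-local frame.
Masses come from the standard residue mass tables (average by default, as
apparent masses from gels are on the average-mass scale; monoisotopic on
request) with one water added per peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from pyteomics import mass as _pmass

from .pattern import AMINO_ACIDS

_AA_SET = frozenset(AMINO_ACIDS)

#: default chymotrypsin specificity: cleavage C-terminal to bulky/hydrophobic residues
CHYMOTRYPSIN_RESIDUES = "FWYLM"

#: mass shift of carbamidomethylation on cysteine (iodoacetamide alkylation)
_CAM = {"average": 57.0513, "monoisotopic": 57.02146}


@lru_cache(maxsize=None)
def _residue_mass(letter: str, mode: str) -> float:
    return _pmass.calculate_mass(sequence=letter, average=(mode == "average")) - water_mass(mode)


@lru_cache(maxsize=None)
def water_mass(mode: str = "average") -> float:
    return _pmass.calculate_mass(formula="H2O", average=(mode == "average"))


@dataclass(frozen=True)
class SegmentSpec:
    """A 1-based inclusive residue range on a named parent sequence."""

    parent_id: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid segment bounds {self.start}..{self.end}")

    def validate_against(self, sequence: str) -> None:
        if self.end > len(sequence):
            raise ValueError(
                f"segment {self.start}..{self.end} exceeds parent length {len(sequence)}"
            )

    def slice(self, sequence: str) -> str:
        self.validate_against(sequence)
        return sequence[self.start - 1 : self.end]

    def __len__(self) -> int:
        return self.end - self.start + 1


def peptide_mass(
    sequence: str,
    mode: str = "average",
    carbamidomethyl_cys: bool = False,
) -> float:
    """Mass of a peptide: residue masses plus one water; optional fixed Cys modification."""
    if mode not in ("average", "monoisotopic"):
        raise ValueError(f"unknown mass mode {mode!r}")
    bad = set(sequence) - _AA_SET
    if bad:
        raise ValueError(f"non-standard residues {''.join(sorted(bad))!r}")
    total = sum(_residue_mass(a, mode) for a in sequence) + water_mass(mode)
    if carbamidomethyl_cys:
        total += sequence.count("C") * _CAM[mode]
    return total


def segment_mass(seg: SegmentSpec, sequence: str, mode: str = "average") -> float:
    """Mass in Da of the segment's residues (one water included)."""
    return peptide_mass(seg.slice(sequence), mode=mode)


def count_residue(seg: SegmentSpec, sequence: str, residue: str) -> int:
    """Exact count of one residue letter within the inclusive span."""
    if residue not in _AA_SET:
        raise ValueError(f"invalid residue letter {residue!r}")
    return seg.slice(sequence).count(residue)


def fragment_boundary_from_mass(
    sequence: str,
    target_mass: float,
    terminus: str = "N",
    mode: str = "average",
) -> tuple[int, float]:
    """Residue index whose terminal fragment mass is closest to ``target_mass``.

    For ``terminus='N'`` returns the 1-based index ``r`` minimizing
    ``|mass(1..r) - target|`` (ties toward the smaller index); for ``'C'``,
    the index ``r`` minimizing ``|mass(r..L) - target|`` (ties toward the
    larger index, i.e. the shorter fragment).  Returns ``(r, residual)``
    where ``residual = mass(fragment) - target``.  The estimate carries no
    information about the actual proteolytic site.
    """
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    L = len(sequence)
    if terminus == "N":
        masses = []
        acc = water_mass(mode)
        for a in sequence:
            acc += _residue_mass(a, mode)
            masses.append(acc)
        indices = range(1, L + 1)
    else:
        masses = []
        acc = water_mass(mode)
        for a in reversed(sequence):
            acc += _residue_mass(a, mode)
            masses.append(acc)
        masses.reverse()
        indices = range(1, L + 1)
    lo, hi = min(masses), max(masses)
    if not lo <= target_mass <= hi:
        raise ValueError(
            f"target mass {target_mass:.1f} Da outside achievable range "
            f"[{lo:.1f}, {hi:.1f}]"
        )
    best_r, best_d = None, None
    for r, mval in zip(indices, masses):
        d = abs(mval - target_mass)
        if best_d is None or d < best_d:  # strict: ties keep the earlier index
            best_r, best_d = r, d
    if terminus == "C":
        # ties toward the shorter fragment = larger start index
        for r, mval in zip(indices, masses):
            if abs(mval - target_mass) == best_d:
                best_r = r
    return best_r, masses[best_r - 1] - target_mass


@dataclass(frozen=True)
class Peptide:
    """A digestion product: 1-based inclusive span and missed-cleavage count."""

    start: int
    end: int
    missed_cleavages: int


@dataclass(frozen=True)
class PeptideSet:
    """Digestion products with the parameters that generated them."""

    parent_id: str
    peptides: tuple[Peptide, ...]
    enzyme_residues: str
    max_missed: int
    no_proline_rule: bool

    def sequences(self, sequence: str) -> list[str]:
        return [sequence[p.start - 1 : p.end] for p in self.peptides]


def chymotryptic_peptides(
    sequence: str,
    max_missed: int = 3,
    enzyme_residues: str = CHYMOTRYPSIN_RESIDUES,
    no_proline_rule: bool = True,
    parent_id: str = "seq",
    min_length: int = 1,
    max_length: int | None = None,
) -> PeptideSet:
    """Enumerate chymotryptic peptides with up to ``max_missed`` missed cleavages.

    Cleavage occurs after each residue in ``enzyme_residues`` (default
    F/W/Y/L/M), suppressed when the following residue is proline if the
    no-proline rule is on.  Peptides are every contiguous run spanning at
    most ``max_missed`` internal cleavage sites, ordered by (start, end).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    L = len(sequence)
    if L == 0:
        raise ValueError("empty sequence")
    sites = [
        i + 1  # boundary after residue i+1 (1-based)
        for i in range(L - 1)
        if sequence[i] in enzyme_residues
        and not (no_proline_rule and sequence[i + 1] == "P")
    ]
    boundaries = [0] + sites + [L]
    peptides = []
    for a in range(len(boundaries) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(boundaries))):
            start, end = boundaries[a] + 1, boundaries[b]
            length = end - start + 1
            if length < min_length or (max_length is not None and length > max_length):
                continue
            peptides.append(Peptide(start, end, missed_cleavages=b - a - 1))
    peptides.sort(key=lambda p: (p.start, p.end))
    return PeptideSet(
        parent_id=parent_id,
        peptides=tuple(peptides),
        enzyme_residues=enzyme_residues,
        max_missed=max_missed,
        no_proline_rule=no_proline_rule,
    )


def fold_coverage(peptides: PeptideSet, fold: SegmentSpec) -> dict:
    """Peptide support for an ordered-fold segment.

    Returns the number of peptides overlapping the fold span by at least one
    residue and the fraction of fold positions covered by at least one
    peptide.
    """
    if peptides.parent_id != fold.parent_id:
        raise ValueError(
            f"peptides are on {peptides.parent_id!r} but fold is on {fold.parent_id!r}"
        )
    covered = [False] * len(fold)
    n_overlapping = 0
    for p in peptides.peptides:
        lo = max(p.start, fold.start)
        hi = min(p.end, fold.end)
        if lo > hi:
            continue
        n_overlapping += 1
        for i in range(lo - fold.start, hi - fold.start + 1):
            covered[i] = True
    return {
        "n_overlapping": n_overlapping,
        "fraction_of_fold_covered": sum(covered) / len(covered),
    }
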
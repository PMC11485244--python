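"""Degenerate residue patterns and their uniqueness statistics.

A pattern derived from cryo-EM side-chain density is an ordered list of
residue classes: positions where the density pins down a single amino acid,
positions where several amino acids are indistinguishable (a bracketed
class such as ``[NMQ]``), and positions with no usable side-chain
information (the wildcard ``X``).  Scanning such a pattern against a
proteome identifies the protein only if the pattern is informative enough
that random sequences are unlikely to match anywhere; the statistics here
quantify that: the per-window match probability under a background model,
the expected number of background hits in a proteome of a given size, and
the Poisson-approximated probability that the true protein is the unique
hit.
"""

from __future__ import annotations

import math
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
FULL_ALPHABET: frozenset = frozenset(AMINO_ACIDS)


class PatternSyntaxError(ValueError):
    """Raised when a pattern string cannot be parsed; carries the offending index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} (at index {index})")
        self.index = index


@dataclass(frozen=True)
class AmbiguityPattern:
    """An ordered sequence of residue classes.

    Each position is a non-empty frozenset over the 20-letter amino-acid
    alphabet; a position equal to the full alphabet is a wildcard.
    """

    positions: tuple[frozenset, ...]

    def __post_init__(self):
        if not self.positions:
            raise ValueError("pattern must have at least one position")
        for i, pos in enumerate(self.positions):
            if not pos:
                raise ValueError(f"empty residue class at position {i}")
            if not pos <= _AA_SET:
                bad = "".join(sorted(pos - _AA_SET))
                raise ValueError(f"non-alphabet residues {bad!r} at position {i}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def class_sizes(self) -> list[int]:
        return [len(p) for p in self.positions]

    def is_wildcard(self, i: int) -> bool:
        return len(self.positions[i]) == len(AMINO_ACIDS)

    def reversed(self) -> "AmbiguityPattern":
        """Pattern with position order reversed (chain-direction ambiguity)."""
        return AmbiguityPattern(tuple(reversed(self.positions)))

    def with_il_equivalence(self) -> "AmbiguityPattern":
        """Every class containing I or L is extended to contain both."""
        il = frozenset("IL")
        new = tuple(
            p | il if (p & il and not p >= il) else p for p in self.positions
        )
        return AmbiguityPattern(new)

    def to_string(self) -> str:
        """Serialize in bracket-class syntax; parse(to_string()) round-trips."""
        out = []
        for pos in self.positions:
            if len(pos) == len(AMINO_ACIDS):
                out.append("X")
            elif len(pos) == 1:
                out.append(next(iter(pos)))
            else:
                out.append("[" + "".join(sorted(pos)) + "]")
        return "".join(out)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_pattern(text: str) -> AmbiguityPattern:
    """Parse a bracket-syntax pattern string.

    Grammar: an uppercase residue letter is a fixed position, ``[...]`` with
    two or more distinct residue letters is a class, and ``X`` is a wildcard
    matching any residue.  Lowercase letters are rejected.

    Raises
    ------
    PatternSyntaxError
        On unclosed brackets, empty or singleton classes, or characters
        outside the amino-acid alphabet; the error names the offending
        string index.
    """
    if not text:
        raise PatternSyntaxError("empty pattern", 0)
    positions: list[frozenset] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == "X":
            positions.append(FULL_ALPHABET)
            i += 1
        elif c in _AA_SET:
            positions.append(frozenset(c))
            i += 1
        elif c == "[":
            j = text.find("]", i + 1)
            if j == -1:
                raise PatternSyntaxError("unclosed bracket", i)
            members = text[i + 1 : j]
            if not members:
                raise PatternSyntaxError("empty residue class", i)
            for k, ch in enumerate(members):
                if ch not in _AA_SET:
                    raise PatternSyntaxError(
                        f"invalid residue {ch!r} in class", i + 1 + k
                    )
            cls = frozenset(members)
            if len(cls) < 2:
                raise PatternSyntaxError(
                    "residue class must contain at least 2 distinct residues", i
                )
            positions.append(cls)
            i = j + 1
        else:
            raise PatternSyntaxError(f"invalid character {c!r}", i)
    return AmbiguityPattern(tuple(positions))


def from_prosite(text: str) -> AmbiguityPattern:
    """Convert a PROSITE-style pattern (``G-[NMQ]-x(2)-[SA]-...``) to bracket syntax.

    Supports dashed elements, ``x`` or ``X`` wildcards with optional ``(n)``
    repetition on any element, and a trailing period.  Negated classes
    (``{...}``) are not supported.
    """
    if not text:
        raise PatternSyntaxError("empty pattern", 0)
    body = text.strip().rstrip(".")
    positions: list[frozenset] = []
    for elem in body.split("-"):
        m = re.fullmatch(r"(x|X|[A-Z]|\[[A-Z]+\])(?:\((\d+)\))?", elem)
        if m is None:
            raise PatternSyntaxError(f"cannot parse PROSITE element {elem!r}", 0)
        token, rep = m.group(1), int(m.group(2) or 1)
        if token in ("x", "X"):
            cls = FULL_ALPHABET
        elif token.startswith("["):
            cls = frozenset(token[1:-1])
            if not cls <= _AA_SET:
                raise PatternSyntaxError(f"invalid residues in {token!r}", 0)
        else:
            if token not in _AA_SET:
                raise PatternSyntaxError(f"invalid residue {token!r}", 0)
            cls = frozenset(token)
        positions.extend([cls] * rep)
    return AmbiguityPattern(tuple(positions))


@dataclass(frozen=True)
class BackgroundModel:
    """Per-residue background frequencies; must sum to 1 within 1e-9."""

    frequencies: Mapping[str, float] = field(hash=False)

    def __post_init__(self):
        keys = frozenset(self.frequencies)
        if keys != _AA_SET:
            raise ValueError("background must assign a frequency to each of the 20 amino acids")
        vals = list(self.frequencies.values())
        if any(v < 0 for v in vals):
            raise ValueError("background frequencies must be non-negative")
        total = sum(vals)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total!r}, not 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls({a: 0.05 for a in AMINO_ACIDS})

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "BackgroundModel":
        """Empirical background from observed residue counts (standard letters only)."""
        counts = {a: 0 for a in AMINO_ACIDS}
        for seq in sequences:
            for ch in seq:
                if ch in counts:
                    counts[ch] += 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no standard residues observed")
        return cls({a: counts[a] / total for a in AMINO_ACIDS})

    def class_probability(self, residue_class: frozenset) -> float:
        return sum(self.frequencies[a] for a in residue_class)


@dataclass(frozen=True)
class MatchStatistics:
    """Background-hit statistics for a pattern scanned over a window count.

    ``p_unique`` is the Poisson probability of zero background hits, i.e. the
    probability that a true-positive match would be the single hit.
    """

    p_window: float
    total_windows: float
    expected_hits: float
    information_bits: float
    p_any_hit: float
    p_unique: float

    def to_dict(self) -> dict:
        return {
            "p_window": self.p_window,
            "total_windows": self.total_windows,
            "expected_hits": self.expected_hits,
            "information_bits": self.information_bits,
            "p_any_hit": self.p_any_hit,
            "p_unique": self.p_unique,
        }


def match_probability(pattern: AmbiguityPattern, background: BackgroundModel | None = None) -> float:
    """Probability that one random background window matches the pattern.

    Positions are independent under the i.i.d. background, so this is the
    product over positions of the class frequency mass; under the uniform
    background it equals ``prod(|class_i| / 20)``.
    """
    bg = background or BackgroundModel.uniform()
    p = 1.0
    for cls in pattern.positions:
        p *= bg.class_probability(cls)
    return p


def information_content(pattern: AmbiguityPattern, background: BackgroundModel | None = None) -> float:
    """Pattern information in bits: sum over positions of -log2(class mass).

    Equals ``-log2(match_probability)`` exactly; zero for an all-wildcard
    pattern under any background.
    """
    bg = background or BackgroundModel.uniform()
    bits = 0.0
    for i, cls in enumerate(pattern.positions):
        q = bg.class_probability(cls)
        if q <= 0.0:
            raise ValueError(
                f"position {i} has zero probability under the background "
                "(class outside background support)"
            )
        bits += -math.log2(q)
    return bits


def expected_hits(
    pattern: AmbiguityPattern,
    total_windows: float,
    background: BackgroundModel | None = None,
) -> MatchStatistics:
    """Expected background hits and uniqueness probabilities for a proteome size.

    ``total_windows`` is the number of pattern-length windows in the scanned
    database, i.e. ``sum(max(0, L - m + 1))`` over sequences.  Hit counts are
    treated as Poisson with mean ``p_window * total_windows``.
    """
    if total_windows < 0:
        raise ValueError("total_windows must be non-negative")
    bg = background or BackgroundModel.uniform()
    p = match_probability(pattern, bg)
    mean = p * total_windows
    return MatchStatistics(
        p_window=p,
        total_windows=total_windows,
        expected_hits=mean,
        information_bits=information_content(pattern, bg),
        p_any_hit=-math.expm1(-mean),
        p_unique=math.exp(-mean),
    )


def count_windows(lengths: Iterable[int], m: int) -> int:
    """Total number of length-``m`` windows over sequences of the given lengths."""
    if m < 1:
        raise ValueError("pattern length must be >= 1")
    return sum(max(0, L - m + 1) for L in lengths)
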
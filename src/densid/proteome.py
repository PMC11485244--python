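"""FASTA proteome I/O and degenerate-pattern scanning.

The scanner tests every window of every sequence against an
:class:`~densid.pattern.AmbiguityPattern`, reporting overlapping hits with
1-based inclusive coordinates.  Matching uses per-position residue bitmasks:
each pattern position is a 20-bit mask over the amino-acid alphabet and a
window matches when every subject residue's bit is set in the corresponding
position mask.  Non-standard subject letters (B, Z, J, U, O, X) carry an
empty mask, so they never satisfy a non-wildcard position but do satisfy
wildcards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .pattern import AMINO_ACIDS, AmbiguityPattern

logger = logging.getLogger(__name__)

#: letters accepted in subject sequences beyond the standard 20
AMBIGUOUS_LETTERS = "BZJUOX"
_VALID_SUBJECT = frozenset(AMINO_ACIDS + AMBIGUOUS_LETTERS)


@dataclass(frozen=True)
class SequenceRecord:
    """One named protein sequence (sanitized residues, standard + ambiguous letters)."""

    identifier: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MatchHit:
    """A pattern match: 1-based inclusive span on a named record."""

    identifier: str
    start: int
    end: int
    matched_subsequence: str


def sanitize_residues(raw: str, identifier: str = "?") -> str:
    """Uppercase, strip ``*`` and gap characters (logged), validate letters."""
    up = raw.upper()
    stripped = up.replace("*", "").replace("-", "").replace(".", "")
    n_removed = len(up) - len(stripped)
    if n_removed:
        logger.warning("%s: stripped %d '*'/gap characters", identifier, n_removed)
    bad = set(stripped) - _VALID_SUBJECT
    if bad:
        raise ValueError(
            f"record {identifier}: invalid residue letters {''.join(sorted(bad))!r}"
        )
    return stripped


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Raises on an empty file, duplicate identifiers, or a record with no
    sequence.  Counts of sanitized (stripped) characters are logged.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    n_ambiguous = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = sanitize_residues(str(rec.seq), rec.id)
        if not residues:
            raise ValueError(f"record {rec.id!r} has no sequence")
        n_ambiguous += sum(residues.count(c) for c in AMBIGUOUS_LETTERS)
        records.append(SequenceRecord(rec.id, rec.description, residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if n_ambiguous:
        logger.info("%s: %d ambiguous residue letters retained", path, n_ambiguous)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records in file order, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.identifier
            if rec.description and rec.description != rec.identifier:
                header = rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _position_masks(pattern: AmbiguityPattern) -> np.ndarray:
    """Boolean matrix (m, 26): entry [i, c] is True iff letter c satisfies position i."""
    m = len(pattern)
    masks = np.zeros((m, 26), dtype=bool)
    for i, cls in enumerate(pattern.positions):
        if len(cls) == len(AMINO_ACIDS):
            masks[i, :] = True  # wildcard: any subject letter, ambiguous included
        else:
            for a in cls:
                masks[i, ord(a) - 65] = True
    return masks


def scan(
    pattern: AmbiguityPattern,
    proteome: list[SequenceRecord],
    reverse: bool = False,
    il_equivalent: bool = False,
) -> list[MatchHit]:
    """Scan the pattern over every window of every record.

    Overlapping hits are all reported, ordered by (record order in the
    input, start).  With ``reverse`` the pattern's position order is
    reversed before scanning (chain-direction ambiguity in density); with
    ``il_equivalent`` isoleucine and leucine are interchangeable at every
    position (their side-chain densities are indistinguishable).
    """
    p = pattern
    if reverse:
        p = p.reversed()
    if il_equivalent:
        p = p.with_il_equivalence()
    masks = _position_masks(p)
    m = len(p)
    hits: list[MatchHit] = []
    for rec in proteome:
        n = len(rec.residues)
        if n < m:
            continue
        codes = np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8) - 65
        nw = n - m + 1
        ok = masks[0][codes[:nw]]
        for i in range(1, m):
            ok &= masks[i][codes[i : i + nw]]
        for start0 in np.flatnonzero(ok):
            s = int(start0)
            hits.append(
                MatchHit(rec.identifier, s + 1, s + m, rec.residues[s : s + m])
            )
    return hits


def count_distinct_proteins(hits: list[MatchHit]) -> int:
    """Number of distinct record identifiers with at least one hit."""
    return len({h.identifier for h in hits})
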
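"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they validate: the scan oracle goes
through the ``re`` module with overlapping lookahead, the digestion oracle
enumerates all substrings, the geometry oracle traces explicit rung
coordinates, and the contact oracle loops over all atom pairs.
"""

from __future__ import annotations

import math
import re

from densid.pattern import AMINO_ACIDS, AmbiguityPattern


def regex_scan(pattern: AmbiguityPattern, records) -> list[tuple[str, int, int, str]]:
    """All (identifier, start, end, match) via an overlapping regex search."""
    parts = []
    for cls in pattern.positions:
        if len(cls) == len(AMINO_ACIDS):
            parts.append(".")  # any subject letter, ambiguity codes included
        else:
            parts.append("[" + "".join(sorted(cls)) + "]")
    rx = re.compile("(?=(" + "".join(parts) + "))")
    m = len(pattern)
    out = []
    for rec in records:
        for match in rx.finditer(rec.residues):
            s = match.start()
            out.append((rec.identifier, s + 1, s + m, match.group(1)))
    return out


def brute_force_digest(
    sequence: str,
    max_missed: int,
    enzyme_residues: str = "FWYLM",
    no_proline_rule: bool = True,
) -> set[tuple[int, int, int]]:
    """All (start, end, missed) peptides by testing every substring."""
    L = len(sequence)

    def cleaves_after(i: int) -> bool:  # after 1-based residue i
        if i < 1 or i >= L:
            return False
        if sequence[i - 1] not in enzyme_residues:
            return False
        if no_proline_rule and sequence[i] == "P":
            return False
        return True

    out = set()
    for start in range(1, L + 1):
        if start != 1 and not cleaves_after(start - 1):
            continue
        for end in range(start, L + 1):
            if end != L and not cleaves_after(end):
                continue
            internal = sum(1 for i in range(start, end) if cleaves_after(i))
            if internal <= max_missed:
                out.add((start, end, internal))
    return out


def traced_crossover(twist_deg: float, rise: float) -> float:
    """Crossover located by generating rung coordinates and unwrapping rotation.

    A marker point at unit radius is stacked rung by rung; the axial height
    at which its accumulated azimuthal rotation reaches 180 degrees is
    found by linear interpolation between the bracketing rungs.
    """
    step = math.radians(abs(twist_deg))
    target = math.pi
    prev_xy = (1.0, 0.0)
    total = 0.0
    k = 0
    while True:
        k += 1
        x = math.cos(k * step)
        y = math.sin(k * step)
        delta = math.atan2(
            prev_xy[0] * y - prev_xy[1] * x, prev_xy[0] * x + prev_xy[1] * y
        )
        total += abs(delta)
        if total >= target:
            over = total - target
            frac = 1.0 - over / abs(delta)
            return (k - 1 + frac) * rise
        prev_xy = (x, y)
        if k > 10_000_000:  # pragma: no cover
            raise RuntimeError("trace did not reach 180 degrees")


def all_pairs_interface(st, range_a, range_b, cutoff):
    """Interface side-chain flags by looping over every atom pair.

    ``range_a``/``range_b`` are ``(chain_id, start, end)``.  Returns a set of
    ``(chain_id, residue_number)`` whose side chains contact the other range.
    """
    backbone = {"N", "CA", "C", "O", "OXT"}
    model = st[0]

    def residues(chain_id, start, end):
        out = []
        for chain in model:
            if chain.name != chain_id:
                continue
            for res in chain:
                if start <= res.seqid.num <= end:
                    out.append(res)
        return out

    def heavy(res, side_only):
        return [
            a for a in res
            if a.element.name not in ("H", "D")
            and (not side_only or a.name not in backbone)
        ]

    flagged = set()
    for (ca, sa, ea), (cb, sb, eb) in ((range_a, range_b), (range_b, range_a)):
        partner_atoms = [a for r in residues(cb, sb, eb) for a in heavy(r, False)]
        for res in residues(ca, sa, ea):
            for atom in heavy(res, True):
                for patom in partner_atoms:
                    if atom.pos.dist(patom.pos) <= cutoff:
                        flagged.add((ca, res.seqid.num))
                        break
                else:
                    continue
                break
    return flagged
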
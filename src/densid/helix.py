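"""Helical symmetry of amyloid filaments: twist/rise vs crossover distance.

An amyloid filament is a stack of rungs related by a rotation (twist, in
degrees) and an axial translation (rise, in Angstrom).  In projection the
filament appears to narrow and widen periodically; the crossover distance
is the axial distance over which the cross-section rotates by 180 degrees,

    crossover = rise * 180 / |twist|,

and is directly measurable in micrographs.  Sign convention: negative
twist means a left-handed helix; the sign never affects the crossover.
"""

from __future__ import annotations

from dataclasses import dataclass

#: canonical cross-beta rung spacing in Angstrom, used only as a documented default
DEFAULT_RISE = 4.75


@dataclass(frozen=True)
class HelicalSymmetry:
    """Twist (degrees per rung, signed; negative = left-handed) and rise (A > 0)."""

    twist: float
    rise: float

    def __post_init__(self):
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not 0 < abs(self.twist) <= 180:
            raise ValueError("|twist| must lie in (0, 180] degrees")

    @property
    def handedness(self) -> str:
        return "left" if self.twist < 0 else "right"

    @property
    def rungs_per_crossover(self) -> float:
        return 180.0 / abs(self.twist)


def crossover_from_symmetry(sym: HelicalSymmetry) -> float:
    """Crossover distance in Angstrom: axial length of a 180-degree rotation."""
    return sym.rise * 180.0 / abs(sym.twist)


def twist_from_crossover(
    crossover: float, rise: float, handedness: str = "left"
) -> HelicalSymmetry:
    """Symmetry whose crossover distance equals the given value.

    ``crossover >= rise`` is required (a single rung cannot rotate by more
    than 180 degrees); handedness fixes the sign of the twist.
    """
    if rise <= 0:
        raise ValueError("rise must be positive")
    if crossover < rise * (1.0 - 1e-12):
        raise ValueError("crossover must be at least one rise")
    if handedness not in ("left", "right"):
        raise ValueError("handedness must be 'left' or 'right'")
    magnitude = min(180.0, rise * 180.0 / crossover)
    twist = -magnitude if handedness == "left" else magnitude
    return HelicalSymmetry(twist=twist, rise=rise)
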
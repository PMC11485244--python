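"""Resolution-tiered amino-acid confusion models and identification-recovery simulation.

At a given local map resolution, several amino acids can be
indistinguishable by their side-chain density alone (serine vs alanine,
asparagine vs glutamine vs methionine, and so on).  A
:class:`ConfusionModel` abstracts density quality as an ordered series of
tiers: tier 1 (best resolved) distinguishes every residue, and successive
tiers merge more residues into common ambiguity classes, down to a final
tier where the side chain carries no information (wildcard).  Deriving a
pattern from a true sequence window then amounts to replacing each residue
by its confusion class at the tier assigned to that position, which is how
a degenerate motif read off a cryo-EM map relates to the underlying
sequence.

``simulate_recovery`` measures, by seeded Monte Carlo, how often a pattern
derived this way identifies its source protein uniquely when scanned
against a decoy proteome.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .pattern import AMINO_ACIDS, AmbiguityPattern, BackgroundModel
from .proteome import MatchHit, SequenceRecord, scan

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ConfusionModel:
    """Ordered tiers of amino-acid indistinguishability.

    ``tiers[0]`` is the best-resolved tier.  Each tier must be a full
    partition of the 20-letter alphabet, and tiers must be ordered by
    refinement: every class at one tier is contained in a single class at
    the next (worse) tier.
    """

    tiers: tuple[tuple[frozenset, ...], ...]

    def __post_init__(self):
        if not self.tiers:
            raise ValueError("model needs at least one tier")
        for t, tier in enumerate(self.tiers, start=1):
            union = set()
            total = 0
            for cls in tier:
                union |= cls
                total += len(cls)
            if union != _AA_SET or total != len(AMINO_ACIDS):
                raise ValueError(f"tier {t} is not a partition of the amino-acid alphabet")
        for t in range(len(self.tiers) - 1):
            coarse = self.tiers[t + 1]
            for cls in self.tiers[t]:
                if not any(cls <= c for c in coarse):
                    raise ValueError(
                        f"tier {t + 2} does not refine tier {t + 1}: "
                        f"class {''.join(sorted(cls))} is split"
                    )

    @property
    def n_tiers(self) -> int:
        return len(self.tiers)

    def class_of(self, residue: str, tier: int) -> frozenset:
        """Confusion class containing ``residue`` at 1-based ``tier``."""
        if residue not in _AA_SET:
            raise ValueError(f"residue {residue!r} outside the amino-acid alphabet")
        if not 1 <= tier <= self.n_tiers:
            raise ValueError(f"tier {tier} out of range 1..{self.n_tiers}")
        for cls in self.tiers[tier - 1]:
            if residue in cls:
                return cls
        raise AssertionError("unreachable: tiers are partitions")


def _complete(classes: list[str]) -> tuple[frozenset, ...]:
    """Build a partition from merged-class strings plus singletons for the rest."""
    merged = [frozenset(c) for c in classes]
    covered = set().union(*merged) if merged else set()
    singles = [frozenset(a) for a in AMINO_ACIDS if a not in covered]
    return tuple(merged + singles)


def identity_model() -> ConfusionModel:
    """Single tier of singletons: every side chain fully resolved."""
    return ConfusionModel((_complete([]),))


def default_confusion_model() -> ConfusionModel:
    """Five-tier model of side-chain ambiguity at worsening resolution.

    Tier 2 merges pairs indistinguishable at modest resolution (isosteric
    I/L, the acid/amide pairs by length, S/A, the β-branched T/V); tier 3
    merges by coarse side-chain shape ([SAG], [NMQ], [WF], [DE], [KR]);
    tier 4 keeps only three density envelopes — long polar/charged
    ([DEKRNQM]), small/aliphatic, and bulky aromatic; tier 5 is a single
    class, i.e. no side-chain information (wildcard).
    """
    return ConfusionModel(
        (
            _complete([]),
            _complete(["SA", "IL", "NQ", "DE", "TV"]),
            _complete(["SAG", "NMQ", "WF", "DE", "KR", "IL", "TV"]),
            (frozenset("DEKRNQM"), frozenset("SAGTVILCP"), frozenset("WFYH")),
            (frozenset(AMINO_ACIDS),),
        )
    )


def derive_pattern(
    window: str,
    model: ConfusionModel,
    tiers: int | Sequence[int] = 1,
) -> AmbiguityPattern:
    """Build the ambiguity pattern a density of given quality would yield.

    ``tiers`` is either one tier applied to every position or a per-position
    sequence of tiers (1 = best resolved).  Each derived class contains the
    true residue by construction (soundness).
    """
    if not window:
        raise ValueError("window must be non-empty")
    if isinstance(tiers, int):
        tier_list = [tiers] * len(window)
    else:
        tier_list = list(tiers)
        if len(tier_list) != len(window):
            raise ValueError("per-position tiers must match the window length")
    return AmbiguityPattern(
        tuple(model.class_of(res, t) for res, t in zip(window, tier_list))
    )


@dataclass(frozen=True)
class RecoveryResult:
    """Aggregate outcome of a recovery simulation (seeded, reproducible)."""

    fraction_unique: float
    fraction_contains_true: float
    replicates: int
    seed: int
    parameters: dict = field(hash=False)

    def __post_init__(self):
        if not 0.0 <= self.fraction_unique <= self.fraction_contains_true <= 1.0:
            raise ValueError("fractions must satisfy 0 <= unique <= contains <= 1")


def _random_proteome(
    rng: np.random.Generator,
    n_sequences: int,
    length: int,
    background: BackgroundModel,
    prefix: str = "decoy",
) -> list[SequenceRecord]:
    freqs = np.array([background.frequencies[a] for a in AMINO_ACIDS])
    letters = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
    records = []
    for i in range(n_sequences):
        idx = rng.choice(len(letters), size=length, p=freqs)
        seq = letters[idx].tobytes().decode("ascii")
        records.append(SequenceRecord(f"{prefix}{i:05d}", f"{prefix}{i:05d}", seq))
    return records


def simulate_recovery(
    true_protein: SequenceRecord,
    m: int,
    model: ConfusionModel,
    n_decoys: int,
    decoy_length: int,
    replicates: int,
    seed: int,
    tiers: int | Sequence[int] = 1,
    background: BackgroundModel | None = None,
    tier_probabilities: Sequence[float] | None = None,
) -> RecoveryResult:
    """Monte-Carlo estimate of unique-identification probability.

    Per replicate ``r`` (seeded with ``seed + r``): draw a decoy proteome of
    ``n_decoys`` i.i.d. sequences from the background, insert the true
    protein at a random position in the record list, choose a random
    length-``m`` window of the true protein, derive a pattern from it under
    the confusion model (fixed per-position ``tiers``, or tiers sampled
    i.i.d. from ``tier_probabilities``), scan the proteome, and record
    whether the true protein is among the hits and whether it is the only
    protein hit.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if m > len(true_protein.residues):
        raise ValueError("window length exceeds the true protein length")
    if n_decoys < 0 or decoy_length < 1:
        raise ValueError("invalid decoy proteome parameters")
    bg = background or BackgroundModel.uniform()
    n_unique = 0
    n_contains = 0
    for r in range(replicates):
        rng = np.random.default_rng(seed + r)
        proteome = _random_proteome(rng, n_decoys, decoy_length, bg)
        insert_at = int(rng.integers(0, len(proteome) + 1))
        proteome.insert(insert_at, true_protein)
        start = int(rng.integers(0, len(true_protein.residues) - m + 1))
        window = true_protein.residues[start : start + m]
        if tier_probabilities is not None:
            tier_list = list(
                rng.choice(
                    np.arange(1, model.n_tiers + 1),
                    size=m,
                    p=np.asarray(tier_probabilities, dtype=float),
                )
            )
            pattern = derive_pattern(window, model, [int(t) for t in tier_list])
        else:
            pattern = derive_pattern(window, model, tiers)
        hits: list[MatchHit] = scan(pattern, proteome)
        ids = {h.identifier for h in hits}
        if true_protein.identifier in ids:
            n_contains += 1
            if len(ids) == 1:
                n_unique += 1
    return RecoveryResult(
        fraction_unique=n_unique / replicates,
        fraction_contains_true=n_contains / replicates,
        replicates=replicates,
        seed=seed,
        parameters={
            "m": m,
            "n_decoys": n_decoys,
            "decoy_length": decoy_length,
            "tiers": tiers if isinstance(tiers, int) else list(tiers),
            "tier_probabilities": (
                list(tier_probabilities) if tier_probabilities is not None else None
            ),
        },
    )


def parse_model_file(path: str) -> ConfusionModel:
    """Read a confusion model from a small text file.

    One tier per line, best tier first; classes are whitespace-separated
    residue strings, e.g. ``SA IL NQ DE TV``.  Residues not listed on a
    line remain singletons at that tier.  Blank lines and ``#`` comments
    are ignored.
    """
    tiers = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tiers.append(_complete(line.split()))
    if not tiers:
        raise ValueError(f"no tiers found in {path}")
    return ConfusionModel(tuple(tiers))
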
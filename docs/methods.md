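# Methods

This note documents the models behind `densid`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical conventions.

## Degenerate patterns and uniqueness statistics

A pattern is an ordered list of m positions, each a non-empty subset Sᵢ of
the 20-residue alphabet (hard sets, not position weights — side-chain
density either admits a residue shape or it does not). The grammar is the
bracket syntax in which such motifs are printed (`G[NMQ]X[SA]...`): an
uppercase letter fixes a position, `[...]` lists a class of at least two
distinct residues, and `X` (only uppercase, to catch typos) is a wildcard
equal to the full alphabet. A PROSITE-style converter (`G-[NMQ]-x(1)-...`)
normalizes dashed patterns to this form. Negated classes and gaps are not
supported. Serialization prints class members in alphabetical order, so
`parse(serialize(p)) == p` for every pattern even though the string may
differ from the original input.

Under an i.i.d. background with residue frequencies f (uniform, f_a = 0.05,
by default — no specific null model is implied by a proteome search — or
empirical frequencies computed from the scanned database), the probability
that one random window matches is

    p = ∏ᵢ Σ_{a∈Sᵢ} f_a ,

the information content is −log₂ p bits (additive per position; 0 for an
all-wildcard pattern), and for a database with N windows
(N = Σ max(0, L − m + 1)) the background hit count is modelled as
Poisson(pN): P(no chance hit) = e^{−pN}. The Poisson approximation ignores
the slight dependence between overlapping windows; at the p ≈ 10⁻⁹ scale
that matters here the effect is negligible. Probability identities are
asserted to 1e-12 relative in tests.

## Scanner

Subject sequences come from FASTA via Biopython. Sanitization: `*` and gap
characters are stripped with a logged count; the ambiguity codes
B, Z, J, U, O, X are retained but deliberately conservative — they satisfy
only wildcard positions, never a residue class, so ambiguous database
entries cannot create spurious identifications. Matching uses per-position
boolean masks over letter codes with a vectorized sliding window; all
overlapping hits are reported as 1-based inclusive spans, ordered by
(record order, start). Two flags mirror the physical ambiguities of reading
a map: `reverse` scans the reversed position order (chain direction can be
ambiguous in intermediate-resolution density), and `il_equivalent` makes I
and L interchangeable (their side chains are isosteric). I/L equivalence is
off by default because a motif that distinguishes M from other aliphatic
shapes was evidently read at a resolution where the distinction was made
deliberately.

## Confusion model

Side-chain ambiguity is abstracted as ordered tiers. Each tier is a full
partition of the alphabet, and tiers are ordered by refinement (classes
only merge as resolution worsens); both properties are validated at
construction. The default five-tier model is:

1. singletons (every residue resolved);
2. {S,A}, {I,L}, {N,Q}, {D,E}, {T,V};
3. {S,A,G}, {N,M,Q}, {W,F}, {D,E}, {K,R}, {I,L}, {T,V};
4. {D,E,K,R,N,Q,M}, {S,A,G,T,V,I,L,C,P}, {W,F,Y,H};
5. one class (wildcard).

This reconstruction is motivated by the classes that actually occur in the
printed 11-residue motif: [SA], [SAG], [NMQ] and [WF] appear verbatim at
tiers 2–3. The printed long-polar class [EDRKQN] cannot coexist with [NMQ]
in any refinement chain of partitions (N and Q would need to sit in two
classes of one tier), which shows that the original per-position class
choices were expert shape judgements, not a single global partition. The
tier-4 class {D,E,K,R,N,Q,M} is the closest partition-consistent
approximation (it adds M, whose density envelope is similar). Pattern
derivation therefore guarantees soundness — every derived class contains
the true residue — rather than exact reproduction of any particular printed
class; per-position tier schedules let a user mimic position-specific map
quality. Custom models can be supplied as small text files (one tier per
line).

## Recovery simulation

`simulate_recovery` asks: given a window of length m read at a given tier
from a true protein, how often is that protein the unique hit against a
decoy proteome? Per replicate r (seeded `seed + r`, so results are
bit-for-bit reproducible and replicates are independent): generate
`n_decoys` i.i.d. background sequences (fixed length by default; log-normal
lengths optional), insert the true protein at a random list position,
choose a random window, derive the pattern, scan, and record uniqueness.
Default study conditions in the acceptance script: 1000 decoys of length
300 (≈ 3×10⁵ windows, large enough that an all-singleton 11-mer has
essentially zero chance of a background hit while coarse tiers do collide),
windows of length 11 as in the identifying motif, 40 replicates. Under the
identity model the observed fraction-unique converges to the
e^{−E_bg} ≈ 1 predicted analytically; under the all-wildcard tier it is 0
whenever any decoy window exists.

## Synthetic stand-in chains

No network access is assumed anywhere, so the package carries two
deterministic, clearly-labelled synthetic chains (`densid.data`) instead of
the real UniProt entries. They encode the published constraints that the
analyses rely on — for the ANXA11-like chain: the proline-rich N-terminal
low-complexity region with the proline-free span 37–70 and single proline
P71; named residues I37, L39, T44, Q51, L54, S55, N60, T64, G66, N69, M70,
P71, Y74 at their published positions; a window (56–66, `GNSSNMSATWG`)
matching the identifying motif; segment 39–74 at ≈3.8 kDa; ≈56 kDa full
length. For the TDP-43-like chain: glycine-rich (284–310), hydrophobic
(311–342) and Q/N-rich (from 343) regions; named residues G282–G284, F289,
R293, G310, M311, A326, Q327, W334, S342, Q343, N345, N352, G357, S409,
S410; segment 284–345 at ≈6.2 kDa (282–345 ≈6.3 kDa). Residues not pinned
by a published constraint were filled once, deterministically, with
region-appropriate compositions and frozen.

What passing tests on these chains show: the arithmetic (masses, counts,
boundaries, digestion, coverage) and the identification pipeline behave
correctly on sequences with the stated properties. What they do not show:
any new fact about the real ANXA11 or TDP-43 sequences — for those, run the
same functions on UniProt P50995/Q13148 and PDB 9FOR.

## Chain arithmetic

Masses use the standard residue tables via pyteomics, average by default
(apparent masses from gels are average-scale; monoisotopic for MS use), one
water per peptide, optional fixed carbamidomethyl-Cys (+57.05 Da).
`fragment_boundary_from_mass` returns the residue index whose N- (or C-)
terminal fragment mass is closest to a target apparent mass, ties broken
toward the shorter fragment, together with the residual; it is a numeric
estimate only — the actual proteolytic site of the ~22 kDa N-terminal
fragment is unknown. Chymotrypsin specificity defaults to cleavage after
F, W, Y, L, M with the no-cleavage-before-proline rule on (the enzyme is
named in the source protocol but not its specificity set; this is the
common broad-specificity convention) — both configurable. Peptides are all
runs spanning ≤ max_missed internal sites (default 3, matching the MS
search parameters the digestion emulates); at 0 missed cleavages the
peptides tile the sequence exactly, which is asserted as an invariant.

## Helical geometry

crossover = rise × 180/|twist|, inverse |twist| = rise × 180/crossover;
negative twist denotes a left-handed filament, and the sign never enters
the crossover. Valid symmetries require rise > 0 and 0 < |twist| ≤ 180°.
The closed form is checked against an independent oracle that stacks rung
coordinates and locates the 180° rotation by unwrapped-angle interpolation,
to 1e-6 relative. The default rise 4.75 Å is the canonical cross-β rung
spacing and is always stated, never silently applied. At the boundary
|twist| = 180° the inverse tolerates 1e-12 relative rounding so the round
trip is exact.

## Interface analysis

Models are read with gemmi (PDB or mmCIF), author numbering and insertion
codes preserved; where alternative conformations exist only the
highest-occupancy conformer of each atom is kept. A side chain (all
non-hydrogen atoms beyond Cα; Cβ included; glycine has none and is never
counted) is "in the interface" when any of its atoms lies within the cutoff
of any heavy atom of the partner range. The default cutoff is 4.5 Å, a
common van-der-Waals contact convention; because no single criterion is
canonical, the cutoff is exposed and reports should be read across
4.0–5.0 Å when a count matters. The default hydrophobic set is
{A, V, L, I, M, F, W, C, P}; tyrosine is classed polar-aromatic and
glycine is excluded for lack of a side chain — both configurable. The
report is symmetric in the two ranges and monotone in the cutoff (asserted
as properties). Hydrogen-bond tests are geometric: donor–acceptor heavy-atom
distance ≤ 3.5 Å, plus a D–H···A angle ≥ 120° when an explicit hydrogen
exists (cryo-EM models usually deposit none, in which case the distance
criterion alone applies and the returned angle is None). Solvent-mediated
contacts list polar (N/O) protein atoms within 3.5 Å of each ordered-water
oxygen. One molecular layer is analysed; rung-stacking interactions along
the helical axis are out of scope.

## Toy structures

The fixture generator builds idealized extended chains (Cα every 3.8 Å,
schematic backbone, Cβ/Cγ pseudo-side-chains pointing toward or away from
the partner chain per residue). These are geometry fixtures, not
stereochemically valid models: they make every interface decision
independently controllable, so the contact logic can be tested against an
all-pairs distance oracle with known ground truth. The bundled interface
demo places 15 side chains in contact, 12 of them hydrophobic (80%) — a
synthetic miniature of a filament-like hydrophobic interface, used by the
demo and the acceptance script.

## Problem sizes and determinism

The acceptance script and tests run at desk scale, chosen so the Monte
Carlo answers are decisive without being slow: stratified 10⁶ draws per
motif position for the match-probability check (relative SE ≈ 0.7%,
compared at 3 SE), a 2000 × 400-residue scan database, and the recovery
conditions above. One integer seed (CLI `--seed`) drives every random
stream; derived seeds stay below 2³¹. All stochastic outputs record their
seed.

## Known limitations

- The confusion model abstracts density quality as discrete tiers; it does
  not process maps, and its default tiers are a reconstruction, not the
  original expert assignments (which provably cannot be expressed as one
  refinement chain — see above).
- The scanner is a naive O(N·m) bitmask scan intended for desk-scale
  databases, not an indexed search engine.
- Interface counts depend on the contact criterion; only sensitivity
  ranges, not a unique count, are defensible for a deposited model.
- The fragment-boundary estimator assumes an unmodified chain and a single
  cleavage; post-translational modifications shift apparent masses.
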
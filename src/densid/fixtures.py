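"""Seeded generators for synthetic proteomes and toy atomic models.

Everything here is deterministic given its seed, so tests and demos can be
reproduced bit for bit.  The toy structure builder produces idealized
extended chains whose side-chain contact geometry is fully controlled by
construction, which makes it a transparent fixture for interface analysis.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .pattern import AMINO_ACIDS, BackgroundModel
from .proteome import SequenceRecord, write_fasta

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def generate_synthetic_proteome(
    n_sequences: int,
    length: int | tuple[float, float],
    seed: int,
    background: BackgroundModel | None = None,
    embed: SequenceRecord | None = None,
) -> list[SequenceRecord]:
    """Generate i.i.d. decoy sequences, optionally embedding a real record.

    ``length`` is either a fixed integer or ``(mu, sigma)`` parameters of a
    log-normal length distribution (lengths of at least 1).  The embedded
    record is inserted at a seeded position in the record list with its
    identifier prefixed ``TARGET|``.
    """
    if n_sequences < 0:
        raise ValueError("n_sequences must be >= 0")
    bg = background or BackgroundModel.uniform()
    rng = np.random.default_rng(seed)
    freqs = np.array([bg.frequencies[a] for a in AMINO_ACIDS])
    letters = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
    if isinstance(length, tuple):
        mu, sigma = length
        if sigma <= 0:
            raise ValueError("log-normal sigma must be positive")
        lengths = np.maximum(1, rng.lognormal(mu, sigma, size=n_sequences).astype(int))
    else:
        if n_sequences > 0 and length < 1:
            raise ValueError("length must be >= 1")
        lengths = np.full(n_sequences, length, dtype=int)
    records = []
    for i, L in enumerate(lengths):
        idx = rng.choice(len(letters), size=int(L), p=freqs)
        seq = letters[idx].tobytes().decode("ascii")
        records.append(SequenceRecord(f"decoy{i:05d}", f"decoy{i:05d} synthetic", seq))
    if embed is not None:
        pos = int(rng.integers(0, len(records) + 1))
        marked = SequenceRecord(
            f"TARGET|{embed.identifier}",
            f"TARGET|{embed.identifier} embedded target",
            embed.residues,
        )
        records.insert(pos, marked)
    return records


def write_synthetic_proteome_fasta(path: str | Path, *args, **kwargs) -> list[SequenceRecord]:
    """Generate with :func:`generate_synthetic_proteome` and write FASTA."""
    records = generate_synthetic_proteome(*args, **kwargs)
    write_fasta(records, path)
    return records


def generate_toy_structure(
    chains: list[tuple[str, str]],
    displacement: float = 7.0,
    flipped: set[tuple[str, int]] | None = None,
    waters: list[tuple[float, float, float]] | None = None,
    ca_spacing: float = 3.8,
) -> gemmi.Structure:
    """Idealized extended-chain model with controllable inter-chain contacts.

    Each ``(chain_id, sequence)`` chain runs along x with alpha carbons
    ``ca_spacing`` apart; successive chains are offset by ``displacement``
    along y.  Side chains (Cbeta, and Cgamma for residues larger than
    alanine/serine) point toward the neighbouring chain, so residue i of
    one chain contacts residue i of the next at small displacements.
    Residues listed in ``flipped`` (by chain id and 1-based number) have
    their side chain pointing away, removing them from any interface.
    Optional water oxygens are placed at the given coordinates.
    """
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    flipped = flipped or set()
    n_chains = len(chains)
    for ci, (chain_id, sequence) in enumerate(chains):
        chain = gemmi.Chain(chain_id)
        y0 = ci * displacement
        # side chains point toward the other chain(s): +y for the first
        # chain, -y for the last, alternating in between
        direction = 1.0 if ci < n_chains - 1 or n_chains == 1 else -1.0
        for i, aa in enumerate(sequence):
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE[aa]
            res.seqid = gemmi.SeqId(i + 1, " ")
            x = i * ca_spacing
            sign = -direction if (chain_id, i + 1) in flipped else direction
            atoms = [
                ("N", "N", (x - 1.2, y0 + 0.5, 0.3)),
                ("CA", "C", (x, y0, 0.0)),
                ("C", "C", (x + 1.2, y0 + 0.5, -0.3)),
                ("O", "O", (x + 1.2, y0 + 1.7, -0.3)),
            ]
            if aa != "G":
                atoms.append(("CB", "C", (x, y0 + sign * 1.53, 0.0)))
            if aa not in ("G", "A", "S"):
                atoms.append(("CG", "C", (x, y0 + sign * 2.9, 0.4)))
            for name, elem, (ax, ay, az) in atoms:
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(elem)
                atom.pos = gemmi.Position(ax, ay, az)
                atom.occ = 1.0
                atom.b_iso = 20.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    if waters:
        wchain = gemmi.Chain("W")
        for wi, (wx, wy, wz) in enumerate(waters):
            res = gemmi.Residue()
            res.name = "HOH"
            res.seqid = gemmi.SeqId(wi + 1, " ")
            atom = gemmi.Atom()
            atom.name = "O"
            atom.element = gemmi.Element("O")
            atom.pos = gemmi.Position(wx, wy, wz)
            atom.occ = 1.0
            atom.b_iso = 30.0
            res.add_atom(atom)
            wchain.add_residue(res)
        model.add_chain(wchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure_pair(st: gemmi.Structure, pdb_path: str | Path, cif_path: str | Path) -> None:
    """Write the same model as both PDB and mmCIF."""
    st.write_pdb(str(pdb_path))
    st.make_mmcif_document().write_file(str(cif_path))


def interface_demo_structure() -> gemmi.Structure:
    """Synthetic two-chain interface fixture mirroring a filament-like contact.

    Chain A (20 residues) and chain B (19 residues) face each other; by
    construction 15 side chains lie in the interface at the default 4.5 A
    cutoff, of which 12 are hydrophobic (80%).  This is a synthetic
    demonstration geometry, not a deposited model.
    """
    # chain A: 8 contact residues (6 hydrophobic: L V I M F A; 2 polar: S N)
    seq_a = "GSLVIMSFANQTGSYKEDGH"
    contacts_a = {3, 4, 5, 6, 7, 8, 9, 10}  # L V I M S F A N
    # chain B: 7 contact residues (6 hydrophobic: L I V F M W; 1 polar: Q)
    seq_b = "GTLIVFMWQSNYGKEDHTG"
    contacts_b = {3, 4, 5, 6, 7, 8, 9}  # L I V F M W Q
    flipped = {("A", i + 1) for i in range(len(seq_a)) if i + 1 not in contacts_a}
    flipped |= {("B", i + 1) for i in range(len(seq_b)) if i + 1 not in contacts_b}
    return generate_toy_structure(
        [("A", seq_a), ("B", seq_b)], displacement=7.0, flipped=flipped
    )
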
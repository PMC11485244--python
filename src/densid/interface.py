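"""Atomic-model interface analysis: contacting side chains, hydrophobic
fraction, hydrogen bonds, and solvent-mediated contacts.

Models are read with gemmi (PDB or mmCIF) preserving author residue
numbering.  A residue's side chain participates in an inter-chain interface
when at least one of its side-chain heavy atoms (all non-hydrogen atoms
beyond the alpha carbon, Cbeta included) lies within a distance cutoff of
any heavy atom of the partner range; glycine, having no side chain, is
never counted.  The hydrophobic fraction of the interface is reported over
a configurable residue set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .chains import SegmentSpec

#: heavy-atom contact cutoff (A); common van-der-Waals contact convention
DEFAULT_CONTACT_CUTOFF = 4.5

#: residues whose side chains are classed hydrophobic; Y is treated as polar
#: aromatic and G has no side chain
HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "CYS", "PRO"})

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def read_structure(path: str | Path, fmt: str | None = None) -> gemmi.Structure:
    """Read a PDB or mmCIF file into a gemmi Structure.

    Author residue numbering and insertion codes are preserved.  Where
    alternative conformations exist, only the highest-occupancy conformer
    of each atom is kept.  Raises ``ValueError`` on unparseable or empty
    files (for mmCIF, gemmi's message includes the offending line).
    """
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    _keep_highest_occupancy(st)
    n_atoms = sum(
        1 for model in st for chain in model for res in chain for _ in res
    )
    if n_atoms == 0:
        raise ValueError(f"{path}: model contains no atoms")
    return st


def _keep_highest_occupancy(st: gemmi.Structure) -> None:
    for model in st:
        for chain in model:
            for res in chain:
                by_name: dict[str, gemmi.Atom] = {}
                for atom in res:
                    prev = by_name.get(atom.name)
                    if prev is None or atom.occ > prev.occ:
                        by_name[atom.name] = atom
                keep = set(id(a) for a in by_name.values())
                for i in reversed(range(len(res))):
                    if id(res[i]) not in keep:
                        del res[i]
                for atom in res:
                    atom.altloc = "\x00"


def _residues_in_range(model: gemmi.Model, chain_id: str, seg: SegmentSpec):
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not present in model")
    out = []
    for res in chain:
        num = res.seqid.num
        if seg.start <= num <= seg.end:
            out.append(res)
    if not out:
        raise ValueError(
            f"no residues of chain {chain_id} fall in {seg.start}..{seg.end}"
        )
    return out


def _heavy_atoms(res: gemmi.Residue, side_chain_only: bool):
    for atom in res:
        if atom.element == gemmi.Element("H") or atom.element == gemmi.Element("D"):
            continue
        if side_chain_only and atom.name in _BACKBONE_ATOMS:
            continue
        yield atom


def _coords(atoms) -> np.ndarray:
    return np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms], dtype=float)


@dataclass(frozen=True)
class InterfaceResidue:
    """Per-residue interface report entry."""

    chain_id: str
    seqid: int
    name: str
    in_interface: bool
    hydrophobic: bool
    min_side_chain_distance: float  # inf when the residue has no side-chain atoms


@dataclass(frozen=True)
class InterfaceReport:
    """Summary of an inter-chain interface between two residue ranges."""

    residues: tuple[InterfaceResidue, ...]
    cutoff: float
    n_interface_side_chains: int
    n_hydrophobic: int
    fraction_hydrophobic: float

    def to_rows(self) -> list[dict]:
        return [
            {
                "chain": r.chain_id,
                "residue": r.seqid,
                "name": r.name,
                "in_interface": r.in_interface,
                "hydrophobic": r.hydrophobic,
                "min_side_chain_distance": r.min_side_chain_distance,
            }
            for r in self.residues
        ]


def interface_side_chains(
    st: gemmi.Structure,
    range_a: tuple[str, SegmentSpec],
    range_b: tuple[str, SegmentSpec],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    hydrophobic_residues: frozenset = HYDROPHOBIC_RESIDUES,
) -> InterfaceReport:
    """Side chains of either range within ``cutoff`` of any heavy atom of the other.

    The report is symmetric in the two ranges: it lists residues of both,
    and the summary counts the union of interface side chains.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    model = st[0]
    chain_a, seg_a = range_a
    chain_b, seg_b = range_b
    res_a = _residues_in_range(model, chain_a, seg_a)
    res_b = _residues_in_range(model, chain_b, seg_b)

    entries: list[InterfaceResidue] = []
    for own, partner, own_chain in (
        (res_a, res_b, chain_a),
        (res_b, res_a, chain_b),
    ):
        partner_atoms = [a for r in partner for a in _heavy_atoms(r, side_chain_only=False)]
        tree = cKDTree(_coords(partner_atoms))
        for res in own:
            sc = list(_heavy_atoms(res, side_chain_only=True))
            if not sc:
                entries.append(
                    InterfaceResidue(own_chain, res.seqid.num, res.name, False,
                                     res.name in hydrophobic_residues, float("inf"))
                )
                continue
            d, _ = tree.query(_coords(sc))
            dmin = float(np.min(d))
            entries.append(
                InterfaceResidue(
                    own_chain, res.seqid.num, res.name,
                    in_interface=dmin <= cutoff,
                    hydrophobic=res.name in hydrophobic_residues,
                    min_side_chain_distance=dmin,
                )
            )
    n_iface = sum(1 for e in entries if e.in_interface)
    n_hydro = sum(1 for e in entries if e.in_interface and e.hydrophobic)
    return InterfaceReport(
        residues=tuple(entries),
        cutoff=cutoff,
        n_interface_side_chains=n_iface,
        n_hydrophobic=n_hydro,
        fraction_hydrophobic=(n_hydro / n_iface) if n_iface else 0.0,
    )


def _find_atom(model: gemmi.Model, chain_id: str, seqid: int, atom_name: str) -> gemmi.Atom:
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not present in model")
    for res in chain:
        if res.seqid.num == seqid:
            atom = res.find_atom(atom_name, "*")
            if atom is None:
                raise ValueError(
                    f"atom {atom_name!r} missing from {chain_id}/{res.name}{seqid}"
                )
            return atom
    raise ValueError(f"residue {seqid} not present in chain {chain_id}")


def hbond_present(
    st: gemmi.Structure,
    donor: tuple[str, int, str],
    acceptor: tuple[str, int, str],
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    donor_hydrogen: tuple[str, int, str] | None = None,
) -> tuple[bool, dict]:
    """Geometric hydrogen-bond test between named donor and acceptor atoms.

    Atom specs are ``(chain_id, residue_number, atom_name)``.  The bond is
    present when the donor-acceptor heavy-atom distance is at most
    ``distance_cutoff`` and, when a donor hydrogen is given (models built
    from cryo-EM maps usually lack them), the D-H...A angle is at least
    ``angle_cutoff`` degrees.  Returns ``(present, geometry)`` with the
    measured distance and angle (``None`` when no hydrogen is available).
    """
    model = st[0]
    d_atom = _find_atom(model, *donor)
    a_atom = _find_atom(model, *acceptor)
    dist = d_atom.pos.dist(a_atom.pos)
    angle = None
    ok = dist <= distance_cutoff
    if donor_hydrogen is not None:
        h_atom = _find_atom(model, *donor_hydrogen)
        angle = float(np.degrees(gemmi.calculate_angle(d_atom.pos, h_atom.pos, a_atom.pos)))
        ok = ok and angle >= angle_cutoff
    return ok, {"distance": float(dist), "angle": angle}


#: residue names treated as ordered solvent
SOLVENT_NAMES = frozenset({"HOH", "DOD", "WAT"})


def solvent_contacts(
    st: gemmi.Structure,
    cutoff: float = 3.5,
    solvent_names: frozenset = SOLVENT_NAMES,
    residue_specs: list[tuple[str, int]] | None = None,
) -> list[dict]:
    """Polar protein atoms within ``cutoff`` of each ordered solvent site.

    Returns one entry per solvent site that contacts at least one polar
    (N/O) protein atom, listing the contacting residues with distances.
    With ``residue_specs`` (pairs of chain id and residue number) only
    those residues are considered.  Models without solvent yield an empty
    list.
    """
    model = st[0]
    solvent_sites = []
    protein_atoms = []
    for chain in model:
        for res in chain:
            if res.name in solvent_names:
                for atom in res:
                    if atom.element == gemmi.Element("O"):
                        solvent_sites.append((chain.name, res.seqid.num, atom))
            else:
                if residue_specs is not None and (chain.name, res.seqid.num) not in residue_specs:
                    continue
                for atom in res:
                    if atom.element in (gemmi.Element("N"), gemmi.Element("O")):
                        protein_atoms.append((chain.name, res.seqid.num, res.name, atom))
    out = []
    for chain_id, num, watom in solvent_sites:
        contacts = []
        for pchain, pnum, pname, patom in protein_atoms:
            d = watom.pos.dist(patom.pos)
            if d <= cutoff:
                contacts.append(
                    {"chain": pchain, "residue": pnum, "name": pname,
                     "atom": patom.name, "distance": float(d)}
                )
        if contacts:
            out.append({"solvent": {"chain": chain_id, "residue": num},
                        "contacts": sorted(contacts, key=lambda c: c["distance"])})
    return out
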
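"""Protein structure representation and interrogation.

A light in-memory model (Structure / Chain / Residue / Atom) parsed from PDB
text via gemmi, with the geometric conventions the rest of the package
relies on: heavy atoms only, single conformer (highest-occupancy altloc),
author residue numbering, and van der Waals radii from a built-in element
table.  Also provides salt-bridge detection between basic side-chain
nitrogens and acidic side-chain oxygens.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np

from ._ideal import AA3_TO_1, STANDARD_AA3

# Heavy-atom van der Waals radii (Å) used for surface calculations.
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70

WATER_NAMES = {"HOH", "WAT", "DOD"}

# Side-chain atoms defining salt bridges. His is included: at neutral pH its
# imidazole can carry charge and His-Asp pairs are functionally ionic here.
BASIC_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) Å
    radius: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.radius <= 0:
            raise ValueError(f"non-positive radius for atom {self.name}")


@dataclasses.dataclass
class Residue:
    name: str
    seq_number: int
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def residue(self, seq_number: int) -> Residue | None:
        for r in self.residues:
            if r.seq_number == seq_number:
                return r
        return None


@dataclasses.dataclass
class Structure:
    id: str
    chains: list[Chain]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def coordinates(self) -> np.ndarray:
        """All atom positions in (chain, residue, atom) order, shape (n, 3)."""
        pos = [a.position for c in self.chains for r in c.residues
               for a in r.atoms]
        return np.array(pos, dtype=float).reshape(-1, 3)

    def atoms(self) -> list[tuple[str, Residue, Atom]]:
        """Flat [(chain_id, residue, atom), ...] in file order."""
        return [(c.chain_id, r, a) for c in self.chains
                for r in c.residues for a in r.atoms]

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "Structure":
        """Rigid-body copy: x -> R x + t."""
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [Atom(a.name, a.element, rot @ a.position + t, a.radius)
                         for a in r.atoms]
                residues.append(Residue(r.name, r.seq_number, atoms))
            chains.append(Chain(c.chain_id, residues))
        return Structure(self.id, chains)


class EmptyStructureError(ValueError):
    pass


def element_radius(element: str) -> float:
    return ELEMENT_RADII.get(element.upper(), DEFAULT_RADIUS)


def read_structure(path: str | Path, model_index: int = 0,
                   keep_waters: bool = False) -> Structure:
    """Read one model from a PDB file.

    Altlocs are resolved to the highest-occupancy conformer (ties: first
    occurrence); hydrogens (and deuterium) are always dropped, waters by
    default.  Residue numbering is the author numbering from the file.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (OSError, RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    if model_index >= len(st):
        raise IndexError(f"model {model_index} not in {path} "
                         f"({len(st)} models)")
    model = st[model_index]
    chains = []
    for ch in model:
        residues = []
        for res in ch:
            if not keep_waters and res.name in WATER_NAMES:
                continue
            # altloc resolution: keep the highest-occupancy copy per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                if at.element.is_hydrogen:
                    continue
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            atoms = []
            for at in res:  # preserve file order
                if at.name in best and best[at.name] is at:
                    pos = np.array([at.pos.x, at.pos.y, at.pos.z])
                    elem = at.element.name.upper()
                    atoms.append(Atom(at.name, elem, pos, element_radius(elem)))
            if atoms:
                residues.append(Residue(res.name, res.seqid.num, atoms))
        if residues:
            chains.append(Chain(ch.name, residues))
    struct = Structure(st.name or path.stem, chains)
    if struct.n_atoms() == 0:
        raise EmptyStructureError(f"no protein atoms in {path}")
    return struct


def write_structure(struct: Structure, path: str | Path) -> None:
    """Write a Structure as single-model PDB text (3-decimal coordinates)."""
    lines = []
    serial = 0
    for chain in struct.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # PDB atom-name column convention
                pad = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.position
                lines.append(
                    f"ATOM  {serial:5d} {pad:<4s} {res.name:<3s} "
                    f"{chain.chain_id:1s}{res.seq_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}      {chain.residues[-1].name:<3s} "
                     f"{chain.chain_id:1s}{chain.residues[-1].seq_number:4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def extract_sequence(struct: Structure, chain_id: str) -> str:
    """1-letter sequence of a chain; non-standard residues map to 'X'."""
    chain = struct.chain(chain_id)
    return "".join(AA3_TO_1.get(r.name, "X") for r in chain.residues)


@dataclasses.dataclass
class SaltBridge:
    donor_chain: str
    donor_seq: int
    donor_res: str
    acceptor_chain: str
    acceptor_seq: int
    acceptor_res: str
    min_distance: float
    same_chain: bool

    def label(self) -> str:
        d1 = AA3_TO_1.get(self.donor_res, "X")
        a1 = AA3_TO_1.get(self.acceptor_res, "X")
        return (f"{d1}{self.donor_seq}({self.donor_chain})-"
                f"{a1}{self.acceptor_seq}({self.acceptor_chain})")


def salt_bridge_scan(struct: Structure, cutoff: float = 4.0) -> list[SaltBridge]:
    """All basic-N / acidic-O side-chain contacts within cutoff.

    One record per (donor residue, acceptor residue) pair carrying the
    minimum N–O distance; results sorted by that distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    donors = []   # (chain_id, residue, [positions])
    acceptors = []
    for chain in struct.chains:
        for res in chain.residues:
            if res.name in BASIC_ATOMS:
                pos = [a.position for a in res.atoms
                       if a.name in BASIC_ATOMS[res.name]]
                if pos:
                    donors.append((chain.chain_id, res, np.array(pos)))
            if res.name in ACIDIC_ATOMS:
                pos = [a.position for a in res.atoms
                       if a.name in ACIDIC_ATOMS[res.name]]
                if pos:
                    acceptors.append((chain.chain_id, res, np.array(pos)))
    bridges = []
    for d_ch, d_res, d_pos in donors:
        for a_ch, a_res, a_pos in acceptors:
            dist = np.linalg.norm(d_pos[:, None, :] - a_pos[None, :, :],
                                  axis=-1)
            dmin = float(dist.min())
            if dmin <= cutoff:
                bridges.append(SaltBridge(
                    donor_chain=d_ch, donor_seq=d_res.seq_number,
                    donor_res=d_res.name,
                    acceptor_chain=a_ch, acceptor_seq=a_res.seq_number,
                    acceptor_res=a_res.name,
                    min_distance=dmin,
                    same_chain=(d_ch == a_ch)))
    bridges.sort(key=lambda b: (b.min_distance, b.donor_chain, b.donor_seq))
    return bridges
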
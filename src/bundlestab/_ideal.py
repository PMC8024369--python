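"""Idealised peptide geometry.

Internal-coordinate (Z-matrix style) templates for backbone and side-chain
heavy atoms of the 20 standard amino acids, and the NeRF placement routine
used to realise them in Cartesian space.  Bond lengths and angles follow the
Engh & Huber consensus values to ~0.01 Å / 1°; side-chain dihedrals default
to extended (trans) rotamers, with planar values for rings and carboxamides.

Used by the extended Gly-X-Gly reference-area calculation, the naive
side-chain placer, and the synthetic helix-bundle generator.  Not intended
for energetic realism — geometry is chemically complete and clash-free for
isolated residues, nothing more.
"""

from __future__ import annotations

import numpy as np

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA3 = set(AA3_TO_1)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D with |C-D| = bond, angle(B,C,D) and dihedral(A,B,C,D).

    Natural extension reference frame (NeRF) construction.
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-10:
        # colinear reference: pick any perpendicular
        probe = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, probe)
        norm_n = np.linalg.norm(n)
    n /= norm_n
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# Backbone geometry (trans peptide)
N_CA = 1.458
CA_C = 1.525
C_N = 1.329
C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8

# C-beta placement off the backbone: improper dihedral C -> N -> CA -> CB
CB_BOND = 1.530
CB_ANGLE = 110.5       # N-CA-CB
CB_IMPROPER = 122.5    # dihedral(C, N, CA, CB); sign gives L-chirality

# Side-chain templates: residue -> list of
#   (atom_name, element, (ref_a, ref_b, ref_c), bond, angle, dihedral)
# Atom D is bonded to ref_c; refs may be backbone or earlier side-chain atoms.
SIDE_CHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, 180.0)],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 114.4, 180.0)],
    "THR": [("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, 180.0),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, -60.0)],
    "VAL": [("CG1", "C", ("N", "CA", "CB"), 1.521, 110.5, 180.0),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, -60.0)],
    "LEU": [("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, 180.0),
            ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, 65.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, -175.0)],
    "ILE": [("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, 180.0),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
            ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, 180.0)],
    "MET": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
            ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
            ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, 180.0)],
    "ASP": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
            ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, 0.0),
            ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, 180.0)],
    "ASN": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
            ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, 0.0),
            ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, 180.0)],
    "GLU": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
            ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, 180.0)],
    "GLN": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
            ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, 180.0)],
    "LYS": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
            ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, 180.0)],
    "ARG": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
            ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
            ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "HIS": [("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, 180.0),
            ("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.354, 131.2, -90.0),
            ("CE1", "C", ("CB", "CG", "ND1"), 1.321, 109.3, 180.0),
            ("NE2", "N", ("CG", "ND1", "CE1"), 1.321, 111.7, 0.0)],
    "PHE": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, 180.0),
            ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.7, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.7, -90.0),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.7, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.7, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0)],
    "TYR": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, 180.0),
            ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.7, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.7, -90.0),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.1, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.1, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
            ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "TRP": [("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, 180.0),
            ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.8, -90.0),
            ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
            ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
            ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
            ("CZ3", "C", ("CG", "CD2", "CE3"), 1.392, 118.6, 180.0),
            ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0)],
    "PRO": [("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, 30.0),
            ("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, -35.0)],
}


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealised C-beta position from backbone N, CA, C (L-chirality)."""
    return place_atom(c, n, ca, CB_BOND, CB_ANGLE, CB_IMPROPER)


def build_side_chain(res_name: str, n: np.ndarray, ca: np.ndarray,
                     c: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """All side-chain heavy atoms (incl. CB) for res_name on a given backbone.

    Returns [(atom_name, element, position), ...]; empty for GLY.
    """
    if res_name == "GLY":
        return []
    coords: dict[str, np.ndarray] = {"N": n, "CA": ca, "C": c}
    coords["CB"] = build_cb(n, ca, c)
    out = [("CB", "C", coords["CB"])]
    for name, elem, (ra, rb, rc), bond, ang, tor in SIDE_CHAINS[res_name]:
        pos = place_atom(coords[ra], coords[rb], coords[rc], bond, ang, tor)
        coords[name] = pos
        out.append((name, elem, pos))
    return out


def build_extended_backbone(n_res: int, phi: float = -120.0,
                            psi: float = 120.0) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O) of an extended chain with given phi/psi.

    Omega fixed trans (180°).  Returns one dict of atom positions per residue.
    """
    residues: list[dict[str, np.ndarray]] = []
    # seed first residue
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANG_N_CA_C)
    c0 = ca0 + CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    residues.append(prev)
    for _ in range(1, n_res):
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], C_N, ANG_CA_C_N, psi)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, N_CA, ANG_C_N_CA, 180.0)
        c_i = place_atom(prev["C"], n_i, ca_i, CA_C, ANG_N_CA_C, phi)
        cur = {"N": n_i, "CA": ca_i, "C": c_i}
        residues.append(cur)
        prev = cur
    # carbonyl oxygens: dihedral N(i+1)-CA-C-O is psi+180; last residue uses psi
    for i, res in enumerate(residues):
        res["O"] = place_atom(res["N"], res["CA"], res["C"], C_O,
                              ANG_CA_C_O, psi + 180.0)
    return residues
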
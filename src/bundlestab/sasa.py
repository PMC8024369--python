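"""Solvent-accessible surface area and the buried-hydrophilic-residue screen.

Per-atom SASA by the Shrake–Rupley method on a deterministic Fibonacci
sphere lattice (default 960 points/atom, 1.4 Å water probe).  Per-residue
relative accessibility normalises each residue's summed area by the area of
the same residue type in an idealised extended Gly-X-Gly tripeptide,
computed once with the same algorithm and probe — never taken from a
literature table, so the ratio is internally consistent.

The screen flags hydrophilic residues whose relative accessibility falls at
or below a threshold (default 0.11) in every chain where the position
occurs; such buried polar/charged residues are candidate sites for
stabilising substitutions in helix-bundle proteins.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from ._ideal import (AA1_TO_3, AA3_TO_1, STANDARD_AA3, build_extended_backbone,
                     build_side_chain)
from .structures import Atom, Chain, EmptyStructureError, Residue, Structure

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960

# Residue classes treated as hydrophilic for the buried-site screen.
HYDROPHILIC_3 = {"ARG", "LYS", "HIS", "ASP", "GLU", "ASN", "GLN",
                 "SER", "THR", "TYR"}


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors from the golden-angle spiral lattice."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(struct: Structure, probe_radius: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_POINTS) -> np.ndarray:
    """Per-atom SASA (Å²) in the order of Structure.atoms()."""
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    coords = struct.coordinates()
    if coords.shape[0] == 0:
        raise EmptyStructureError("cannot compute SASA of an empty structure")
    radii = np.array([a.radius for _, _, a in struct.atoms()])
    return _sasa_points(coords, radii, probe_radius, n_points)


def _sasa_points(coords: np.ndarray, radii: np.ndarray, probe: float,
                 n_points: int) -> np.ndarray:
    sphere = fibonacci_sphere(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        r_i = ext[i]
        pts = coords[i] + r_i * sphere
        # neighbours whose extended sphere could occlude any test point
        nbrs = tree.query_ball_point(coords[i], r_i + max_ext)
        nbrs = [j for j in nbrs if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
            if not exposed.any():
                break
        areas[i] = 4.0 * np.pi * r_i ** 2 * exposed.sum() / n_points
    return areas


def build_gxg(res_name: str) -> Structure:
    """Idealised extended Gly-X-Gly tripeptide (phi=-120°, psi=120°)."""
    from .structures import element_radius
    backbone = build_extended_backbone(3)
    names3 = ["GLY", res_name, "GLY"]
    residues = []
    for i, (bb, name) in enumerate(zip(backbone, names3), start=1):
        atoms = [Atom("N", "N", bb["N"], element_radius("N")),
                 Atom("CA", "C", bb["CA"], element_radius("C")),
                 Atom("C", "C", bb["C"], element_radius("C")),
                 Atom("O", "O", bb["O"], element_radius("O"))]
        for an, el, pos in build_side_chain(name, bb["N"], bb["CA"], bb["C"]):
            atoms.append(Atom(an, el, pos, element_radius(el)))
        residues.append(Residue(name, i, atoms))
    return Structure(f"GXG-{res_name}", [Chain("A", residues)])


@lru_cache(maxsize=64)
def gxg_reference_asa(res_name: str, probe_radius: float = DEFAULT_PROBE,
                      n_points: int = DEFAULT_POINTS) -> float:
    """Total SASA (Å²) of residue X in the extended G-X-G tripeptide."""
    if res_name not in STANDARD_AA3:
        raise KeyError(f"no reference geometry for residue {res_name!r}")
    gxg = build_gxg(res_name)
    areas = shrake_rupley_sasa(gxg, probe_radius, n_points)
    flat = gxg.atoms()
    return float(sum(area for (cid, res, atom), area in zip(flat, areas)
                     if res.seq_number == 2))


@dataclasses.dataclass
class ResidueAccessibility:
    chain_id: str
    seq_number: int
    residue_name: str
    asa: float              # Å²
    asa_gxg: float | None   # Å²; None when no reference exists
    asa_ratio: float | None
    hydrophilic: bool
    buried: bool


def residue_relative_asa(struct: Structure,
                         probe_radius: float = DEFAULT_PROBE,
                         n_points: int = DEFAULT_POINTS,
                         threshold: float = 0.11,
                         hydrophilic_set: set[str] = HYDROPHILIC_3,
                         ) -> list[ResidueAccessibility]:
    """Per-residue ASA, GXG-relative ratio, and buried/hydrophilic flags.

    ASA is computed in the context of the full structure; non-standard
    residues get no reference and an undefined ratio (excluded from any
    screen).  Ratios may exceed 1 for highly exposed termini.
    """
    areas = shrake_rupley_sasa(struct, probe_radius, n_points)
    flat = struct.atoms()
    per_res: dict[tuple[str, int], float] = {}
    res_names: dict[tuple[str, int], str] = {}
    for (cid, res, atom), area in zip(flat, areas):
        key = (cid, res.seq_number)
        per_res[key] = per_res.get(key, 0.0) + float(area)
        res_names[key] = res.name
    out = []
    for (cid, num), asa in per_res.items():
        name = res_names[(cid, num)]
        if name in STANDARD_AA3:
            ref = gxg_reference_asa(name, probe_radius, n_points)
            ratio = asa / ref
        else:
            ref = None
            ratio = None
        hydrophilic = name in hydrophilic_set
        buried = ratio is not None and ratio <= threshold
        out.append(ResidueAccessibility(cid, num, name, asa, ref, ratio,
                                        hydrophilic, buried))
    return out


def find_buried_hydrophilic(accessibilities: list[ResidueAccessibility],
                            threshold: float = 0.11,
                            require_both_chains: bool = True) -> list[int]:
    """Sequence positions of buried hydrophilic residues.

    With require_both_chains, a position qualifies only if the criterion
    (hydrophilic and asa_ratio <= threshold) holds in every chain in which
    the position occurs — the convention for a symmetric homodimer.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    by_pos: dict[int, list[ResidueAccessibility]] = {}
    for acc in accessibilities:
        by_pos.setdefault(acc.seq_number, []).append(acc)
    hits = []
    for pos, accs in by_pos.items():
        ok = [a.hydrophilic and a.asa_ratio is not None
              and a.asa_ratio <= threshold for a in accs]
        if require_both_chains:
            qualified = all(ok)
        else:
            qualified = any(ok)
        if qualified and ok:
            hits.append(pos)
    return sorted(hits)
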
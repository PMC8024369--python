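"""Sequence-derived physical constants and SEC–MALS peak interpretation.

Monomer mass and A280 extinction coefficients are computed from the amino
acid sequence; each SEC–MALS elution peak, characterised by an absolute
weight-average molecular mass, is assigned the oligomeric number whose
multiple of the monomer mass comes closest.
"""

from __future__ import annotations

import dataclasses
import math

# Average residue masses (Da) of the free amino acids; peptide-bond water
# (18.01528 Da per bond) is subtracted on polymerisation.
AA_MASS = {
    "A": 89.0932, "R": 174.2010, "N": 132.1179, "D": 133.1027,
    "C": 121.1582, "Q": 146.1445, "E": 147.1293, "G": 75.0666,
    "H": 155.1546, "I": 131.1729, "L": 131.1729, "K": 146.1876,
    "M": 149.2113, "F": 165.1891, "P": 115.1305, "S": 105.0926,
    "T": 119.1192, "W": 204.2252, "Y": 181.1885, "V": 117.1463,
}
WATER_MASS = 18.01528

# A280 molar absorptivities (M^-1 cm^-1) per aromatic residue, as used for
# concentration determination of the bundle proteins.
EPS_TRP = 5559.0
EPS_TYR = 1197.0
EPS_PHE = 0.7


@dataclasses.dataclass
class SequenceProperties:
    sequence: str
    monomer_mass: float   # kDa
    eps_molar: float      # M^-1 cm^-1
    eps_mass: float       # mL mg^-1 cm^-1
    a280_usable: bool     # False when the sequence has no W/Y/F


@dataclasses.dataclass
class OligomerAssignment:
    peak_id: str
    mw: float                # kDa
    oligomeric_number: int
    mass_fraction: float     # % of total
    residual: float          # |mw - n*monomer| / monomer, in monomer units


def monomer_mass_kda(sequence: str) -> float:
    """Average molecular mass of the polypeptide in kDa."""
    try:
        total = sum(AA_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"non-standard amino acid {exc.args[0]!r}") from exc
    total -= WATER_MASS * (len(sequence) - 1)
    return total / 1000.0


def extinction_coefficient(sequence: str) -> SequenceProperties:
    """Molar and mass extinction coefficients at 280 nm plus monomer mass."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(AA_MASS)
    if bad:
        raise ValueError(f"non-standard amino acids: {sorted(bad)}")
    eps = (EPS_TRP * sequence.count("W") + EPS_TYR * sequence.count("Y")
           + EPS_PHE * sequence.count("F"))
    mass = monomer_mass_kda(sequence)
    eps_mass = eps / (mass * 1000.0)  # mL mg^-1 cm^-1
    return SequenceProperties(sequence, mass, eps, eps_mass,
                              a280_usable=eps > 0)


def oligomer_number(mw: float, monomer_mass: float) -> int:
    """Nearest integer multiple of the monomer mass (ties round up, min 1)."""
    if mw <= 0 or monomer_mass <= 0:
        raise ValueError("masses must be positive")
    return max(1, math.floor(mw / monomer_mass + 0.5))


def assign_peaks(peaks: list[tuple[str, float, float]], monomer_mass: float,
                 ) -> tuple[list[OligomerAssignment], list[str]]:
    """Assign oligomeric numbers to SEC–MALS peaks.

    peaks: [(peak_id, mw_kda, mass_fraction_pct), ...] in elution order,
    which is preserved.  Returns (assignments, warnings); a warning is
    emitted when the mass fractions do not total 100 ± 1%.
    """
    warnings = []
    out = []
    for peak_id, mw, frac in peaks:
        if frac < 0:
            raise ValueError(f"negative mass fraction for peak {peak_id}")
        n = oligomer_number(mw, monomer_mass)
        residual = abs(mw - n * monomer_mass) / monomer_mass
        out.append(OligomerAssignment(peak_id, mw, n, frac, residual))
    total = sum(p[2] for p in peaks)
    if not 99.0 <= total <= 101.0:
        warnings.append(f"mass fractions total {total:.1f}%, not 100%")
    return out, warnings
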
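"""In-silico saturation mutagenesis: candidate enumeration, mutant-structure
construction via a pluggable side-chain placer, and post-scoring filters.

The homodimer convention applies throughout: one mutation spec substitutes
the same sequence position in every chain.  The built-in placer rebuilds
side chains with idealised internal coordinates along the wild-type Cβ
direction — deliberately naive (no rotamer search, no clash relief); the
placer interface accepts externally modelled structures when higher quality
is needed.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable

import numpy as np

from ._ideal import AA1_TO_3, AA3_TO_1, SIDE_CHAINS, build_side_chain
from .structures import Atom, Chain, Residue, Structure, element_radius

AA20 = "ACDEFGHIKLMNPQRSTVWY"

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")


@dataclasses.dataclass(frozen=True)
class MutationSpec:
    site: int          # author sequence position, applied to all chains
    wild_type: str     # 1-letter
    mutant: str        # 1-letter

    def __post_init__(self):
        if self.wild_type == self.mutant:
            raise ValueError("wild type and mutant are identical")
        if self.mutant not in AA20 or self.wild_type not in AA20:
            raise ValueError("mutation must use the 20 standard amino acids")

    @property
    def label(self) -> str:
        return f"{self.wild_type}{self.site}{self.mutant}"


@dataclasses.dataclass
class CandidateSet:
    sites: list[int]
    specs: list[MutationSpec]
    includes_wild_type: bool

    def labels(self) -> list[str]:
        labs = [s.label for s in self.specs]
        if self.includes_wild_type:
            labs = ["WT"] + labs
        return labs


def enumerate_saturation(struct: Structure, sites: Iterable[int],
                         include_wild_type: bool = True) -> CandidateSet:
    """All 19 single substitutions per site, plus the wild-type control.

    Deterministic ordering: sites ascending, mutant amino acid alphabetical.
    Requires each site to exist with the same residue type in every chain.
    """
    sites = sorted(set(sites))
    specs = []
    for site in sites:
        wt_names = set()
        for chain in struct.chains:
            res = chain.residue(site)
            if res is None:
                raise KeyError(f"site {site} missing from chain "
                               f"{chain.chain_id}")
            wt_names.add(res.name)
        if len(wt_names) > 1:
            raise ValueError(f"wild-type mismatch across chains at site "
                             f"{site}: {sorted(wt_names)}")
        wt1 = AA3_TO_1.get(wt_names.pop())
        if wt1 is None or wt1 == "X":
            raise ValueError(f"non-standard wild type at site {site}")
        for aa in AA20:
            if aa != wt1:
                specs.append(MutationSpec(site, wt1, aa))
    return CandidateSet(sites, specs, include_wild_type)


def apply_mutation_sequence(seq: str, spec: MutationSpec) -> str:
    """Apply a substitution to a 1-letter sequence (1-based position)."""
    idx = spec.site - 1
    if not 0 <= idx < len(seq):
        raise IndexError(f"site {spec.site} outside sequence of length "
                         f"{len(seq)}")
    if seq[idx] != spec.wild_type:
        raise ValueError(f"wild-type mismatch at {spec.site}: expected "
                         f"{spec.wild_type}, found {seq[idx]}")
    return seq[:idx] + spec.mutant + seq[idx + 1:]


def naive_placer(residue: Residue, new_name3: str) -> Residue:
    """Rebuild the side chain of residue as new_name3 on its own backbone.

    Idealised internal coordinates grown from the actual N/CA/C positions;
    the new Cβ therefore points along the wild-type Cβ direction.  Backbone
    atoms (N, CA, C, O, OXT) are carried over untouched.
    """
    n, ca, c = (residue.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise ValueError(f"residue {residue.seq_number} lacks a complete "
                         "backbone for side-chain placement")
    atoms = [a for a in residue.atoms if a.name in BACKBONE_ATOMS]
    for an, el, pos in build_side_chain(new_name3, n.position, ca.position,
                                        c.position):
        atoms.append(Atom(an, el, pos, element_radius(el)))
    return Residue(new_name3, residue.seq_number, atoms)


Placer = Callable[[Residue, str], Residue]


def build_mutant_structure(struct: Structure, spec: MutationSpec,
                           placer: Placer = naive_placer) -> Structure:
    """Mutated copy of a homodimer structure: spec applied in every chain."""
    new3 = AA1_TO_3[spec.mutant]
    chains = []
    for chain in struct.chains:
        residues = []
        for res in chain.residues:
            if res.seq_number == spec.site:
                wt1 = AA3_TO_1.get(res.name, "X")
                if wt1 != spec.wild_type:
                    raise ValueError(
                        f"wild-type mismatch at {spec.site} in chain "
                        f"{chain.chain_id}: expected {spec.wild_type}, "
                        f"found {wt1}")
                try:
                    residues.append(placer(res, new3))
                except Exception as exc:
                    raise RuntimeError(
                        f"side-chain placement failed for {spec.label} in "
                        f"chain {chain.chain_id}") from exc
            else:
                residues.append(res)
        chains.append(Chain(chain.chain_id, residues))
    return Structure(f"{struct.id}_{spec.label}", chains)


@dataclasses.dataclass
class FilterRules:
    helical_sites: frozenset[int] = frozenset()
    glycine_rule: bool = True
    variability_factor: float = 2.0


def filter_candidates(scores: list, rules: FilterRules | None = None) -> list:
    """Flag (never delete) candidates failing the selection filters.

    Flags added to MutantScore.flags:
      - ``gly_helix``: glycine substitution at a declared helical site
        (helix-breaking propensity);
      - ``high_variability``: replicate std above variability_factor times
        the median replicate std of candidates at the same site.
    Selection downstream operates on unflagged candidates only.
    """
    rules = rules or FilterRules()
    by_site: dict[int | None, list[float]] = {}
    for sc in scores:
        by_site.setdefault(_site_of(sc.label), []).append(sc.std_rmsd)
    med = {site: float(np.median(v)) for site, v in by_site.items()}
    out = []
    for sc in scores:
        flags = set(sc.flags)
        site = _site_of(sc.label)
        if (rules.glycine_rule and sc.label and sc.label[-1] == "G"
                and site in rules.helical_sites):
            flags.add("gly_helix")
        ceiling = rules.variability_factor * med[site]
        if ceiling > 0 and sc.std_rmsd > ceiling:
            flags.add("high_variability")
        out.append(dataclasses.replace(sc, flags=flags))
    return out


def _site_of(label: str) -> int | None:
    digits = "".join(ch for ch in label if ch.isdigit())
    return int(digits) if digits else None
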
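"""Classification of protein-ligand atomic contacts, approximate contact
surface areas, and conserved-interaction fractions between two complexes.

Atoms are binned into five classes (hydrophilic N/O, aliphatic carbon,
aromatic carbon, sulfur, other) and each contacting pair maps through a
symmetric compatibility matrix to one of five interaction types:
hydrophilic, hydrophobic, aromatic, neutral, unfavorable.  A hydrophilic
pair counts as a hydrogen bond only within donor-acceptor distance
(<= 3.35 A); beyond that it is neutral.

The contact surface area (CSA) is a documented approximation: the spherical
cap cut on the solvent-expanded protein-atom sphere (radius + 1.4 A) by the
radical plane of the expanded ligand-atom sphere.  Because the probe radii
sum to the 2.8 A contact allowance, the area vanishes continuously exactly
at the contact cutoff.  Caps competing for one protein atom are rescaled so
their sum never exceeds the expanded hemisphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import pi

import numpy as np

from .errors import DomainError, PocketspaceError
from .structure_io import (
    AtomRecord,
    ContactRecord,
    DEFAULT_FALLBACK_RADIUS,
    DEFAULT_VDW_RADII,
    HetGroup,
    Structure,
    find_contacts,
)

PROBE_RADIUS = 1.4  # A; 2 * 1.4 = the 2.8 A contact allowance

HBOND_MAX_DISTANCE = 3.35  # A, donor-acceptor upper bound

CONTACT_TYPES = ("hydrophilic", "hydrophobic", "aromatic", "neutral", "unfavorable")

# Aromatic side-chain carbons by residue (one-letter); ring N atoms stay hydrophilic.
_AROMATIC_PROTEIN_ATOMS: dict[str, frozenset[str]] = {
    "F": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "Y": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "W": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "H": frozenset({"CG", "CD2", "CE1"}),
}


def classify_atom(atom: AtomRecord, residue_aa: str | None = None,
                  aromatic: bool = False) -> str:
    """Atom class: hydrophilic / aliphatic / aromatic / sulfur / other."""
    el = atom.element.upper()
    if el in ("N", "O"):
        return "hydrophilic"
    if el == "C":
        if aromatic:
            return "aromatic"
        if residue_aa and atom.name in _AROMATIC_PROTEIN_ATOMS.get(residue_aa, ()):
            return "aromatic"
        return "aliphatic"
    if el == "S":
        return "sulfur"
    if el not in ("P", "F", "CL", "BR", "I", "SE", "B", "H"):
        warnings.warn(f"unknown element {el!r}; classified as 'other'")
    return "other"


def _pair_type(class_a: str, class_b: str, distance: float) -> str:
    """Symmetric class-pair -> interaction type lookup."""
    pair = frozenset((class_a, class_b))
    if pair == {"hydrophilic"}:
        return "hydrophilic" if distance <= HBOND_MAX_DISTANCE else "neutral"
    if "other" in pair:
        return "neutral"
    if pair == {"aromatic"}:
        return "aromatic"
    if pair <= {"aliphatic", "aromatic", "sulfur"}:
        return "hydrophobic"
    if "hydrophilic" in pair and pair & {"aliphatic", "aromatic"}:
        return "unfavorable"
    # remaining: sulfur with hydrophilic
    return "neutral"


def classify_contact(protein_atom: AtomRecord, ligand_atom: AtomRecord,
                     distance: float | None = None,
                     protein_aa: str | None = None,
                     ligand_aromatic: bool = False) -> str:
    """Interaction type of one protein-atom/ligand-atom contact."""
    if distance is None:
        distance = float(np.linalg.norm(protein_atom.pos - ligand_atom.pos))
    ca = classify_atom(protein_atom, residue_aa=protein_aa)
    cb = classify_atom(ligand_atom, aromatic=ligand_aromatic)
    return _pair_type(ca, cb, distance)


# ---------------------------------------------------------------------------
# Contact surface area
# ---------------------------------------------------------------------------

def _expanded_radius(atom: AtomRecord, radii: dict[str, float]) -> float:
    return radii.get(atom.element.upper(), DEFAULT_FALLBACK_RADIUS) + PROBE_RADIUS


def _raw_cap_area(Ra: float, Rb: float, d: float) -> float:
    """Area of the cap cut on sphere A by the radical plane of spheres A, B."""
    if d >= Ra + Rb:
        return 0.0
    if d <= 1e-9 or d + Ra <= Rb:
        return 2.0 * pi * Ra * Ra  # A engulfed: expose a hemisphere-equivalent
    h = Ra - (d * d + Ra * Ra - Rb * Rb) / (2.0 * d)
    h = float(np.clip(h, 0.0, 2.0 * Ra))
    return 2.0 * pi * Ra * h


def contact_surface_area(
    protein_atom: AtomRecord,
    ligand_atom: AtomRecord,
    neighbors: list[AtomRecord] | None = None,
    radii: dict[str, float] | None = None,
) -> float:
    """Approximate CSA (A^2) of one contact.

    ``neighbors``: other ligand atoms competing for the same protein atom;
    when their caps would jointly exceed the expanded hemisphere the areas
    are rescaled proportionally.
    """
    radii = DEFAULT_VDW_RADII if radii is None else radii
    Ra = _expanded_radius(protein_atom, radii)
    d = float(np.linalg.norm(protein_atom.pos - ligand_atom.pos))
    area = _raw_cap_area(Ra, _expanded_radius(ligand_atom, radii), d)
    if not neighbors:
        return area
    total = area
    for nb in neighbors:
        dn = float(np.linalg.norm(protein_atom.pos - nb.pos))
        total += _raw_cap_area(Ra, _expanded_radius(nb, radii), dn)
    hemisphere = 2.0 * pi * Ra * Ra
    if total > hemisphere > 0:
        area *= hemisphere / total
    return area


# ---------------------------------------------------------------------------
# Interface annotation
# ---------------------------------------------------------------------------

def annotate_contacts(
    structure: Structure,
    ligand: HetGroup,
    contacts: list[ContactRecord] | None = None,
    radii: dict[str, float] | None = None,
    ligand_aromatic_atoms: frozenset[str] = frozenset(),
) -> list[ContactRecord]:
    """Fill contact_type and csa on every contact of one complex."""
    if contacts is None:
        contacts = find_contacts(structure, ligand, radii=radii)
    aa_of: dict[tuple, str] = {}
    for ch in structure.chains:
        for res in ch.residues:
            aa_of[res.key] = res.aa
    by_protein_atom: dict[tuple, list[ContactRecord]] = {}
    for c in contacts:
        by_protein_atom.setdefault((c.residue_key, c.protein_atom.name), []).append(c)
    for group in by_protein_atom.values():
        lig_atoms = [c.ligand_atom for c in group]
        for c in group:
            c.contact_type = classify_contact(
                c.protein_atom, c.ligand_atom, c.distance,
                protein_aa=aa_of.get(c.residue_key),
                ligand_aromatic=c.ligand_atom.name in ligand_aromatic_atoms,
            )
            others = [a for a in lig_atoms if a is not c.ligand_atom]
            c.csa = contact_surface_area(c.protein_atom, c.ligand_atom, others, radii)
    return contacts


# ---------------------------------------------------------------------------
# Conserved interactions
# ---------------------------------------------------------------------------

@dataclass
class ConservedFractionResult:
    fractions: dict[str, float]  # per type; absent types are simply missing
    s_p1: dict[str, float]  # total CSA by type, complex 1
    s_p2: dict[str, float]
    s_cons: dict[str, float]


def _area_by_residue_type(contacts: list[ContactRecord]) -> dict[tuple, float]:
    out: dict[tuple, float] = {}
    for c in contacts:
        if c.contact_type is None or c.csa is None:
            raise PocketspaceError("contacts must be annotated (type + csa) first")
        key = (c.residue_key, c.contact_type)
        out[key] = out.get(key, 0.0) + c.csa
    return out


def conserved_fraction(
    contacts_1: list[ContactRecord],
    contacts_2: list[ContactRecord],
    correspondence: dict[tuple, tuple] | None = None,
) -> ConservedFractionResult:
    """Fraction of interactions of each type conserved between two complexes.

    A contact is conserved when the corresponding pocket residue makes a
    contact of the same type in both complexes; its conserved area is the
    smaller of the two sides.  f_i = S_cons_i / mean(S_p1_i, S_p2_i).
    ``correspondence`` maps complex-1 residue keys to complex-2 keys
    (identity when None, i.e. same-protein pairs).
    """
    a1 = _area_by_residue_type(contacts_1)
    a2 = _area_by_residue_type(contacts_2)
    if correspondence is not None:
        a1 = {
            (correspondence[res], typ): v
            for (res, typ), v in a1.items()
            if res in correspondence
        }
    types = {t for _, t in a1} | {t for _, t in a2}
    s1 = {t: 0.0 for t in types}
    s2 = {t: 0.0 for t in types}
    cons = {t: 0.0 for t in types}
    for (res, t), v in a1.items():
        s1[t] += v
    for (res, t), v in a2.items():
        s2[t] += v
    for (res, t), v in a1.items():
        other = a2.get((res, t))
        if other is not None:
            cons[t] += min(v, other)
    fractions = {}
    for t in types:
        denom = 0.5 * (s1[t] + s2[t])
        if denom > 0:
            fractions[t] = float(np.clip(cons[t] / denom, 0.0, 1.0))
    return ConservedFractionResult(fractions, s1, s2, cons)


def interaction_composition(contacts: list[ContactRecord]) -> dict[str, float]:
    """Per-type fraction of the total contact surface area; fractions sum to 1."""
    totals: dict[str, float] = {}
    for c in contacts:
        if c.contact_type is None or c.csa is None:
            raise PocketspaceError("contacts must be annotated (type + csa) first")
        totals[c.contact_type] = totals.get(c.contact_type, 0.0) + c.csa
    grand = sum(totals.values())
    if grand <= 0:
        raise DomainError("no contact surface area; empty or unannotated contact set")
    return {t: v / grand for t, v in sorted(totals.items())}
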
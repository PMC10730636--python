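"""Reconstruction of stoichiometrically correct molecular ensembles.

Starting from an asymmetric unit, this module expands atoms over the
crystal symmetry operators, resolves positional disorder to a single
representative conformation, traces covalently connected networks across
lattice translations (detecting polymers on the way) and reduces the
result to a minimal grouping of crystallographically independent entities
in their stoichiometric ratio.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from . import chem_tables
from .cif_io import (AtomSite, CrystalDescription, apply_symop,
                     cartesian_matrix)

__all__ = [
    "ExpandedAtom",
    "MolecularEntity",
    "StoichiometricEnsemble",
    "expand_to_unit_cell",
    "resolve_positional_disorder",
    "grow_entities",
    "build_ensemble",
    "default_bond_fn",
    "write_xyz",
]

DEFAULT_MERGE_TOL = 0.01      # Angstrom, special-position deduplication
DEFAULT_BOND_TOLERANCE = 0.4  # Angstrom over the covalent-radii sum
DEFAULT_MAX_BOND_CUTOFF = 4.0  # Angstrom hard cap on any bond
DEFAULT_MAX_POLYMER_ATOMS = 400

#: Space-group numbers of the 65 Sohncke groups (chirality-compatible).
SOHNCKE_GROUPS = frozenset(
    [1, 3, 4, 5, 16, 17, 18, 19, 20, 21, 22, 23, 24, 75, 76, 77, 78, 79, 80,
     89, 90, 91, 92, 93, 94, 95, 96, 97, 98, 143, 144, 145, 146, 149, 150,
     151, 152, 153, 154, 155, 168, 169, 170, 171, 172, 173, 177, 178, 179,
     180, 181, 182, 195, 196, 197, 198, 199, 207, 208, 209, 210, 211, 212,
     213, 214])


@dataclass(frozen=True)
class ExpandedAtom:
    site_ref: str
    element: str
    frac: tuple[float, float, float]
    cart: tuple[float, float, float]
    generating_op: int
    lattice_shift: tuple[int, int, int] = (0, 0, 0)
    occupancy: float = 1.0
    attached_hydrogens: int = 0
    disorder_assembly: str | None = None
    disorder_group: str | None = None

    @property
    def key(self) -> tuple:
        return (self.site_ref, self.generating_op, self.lattice_shift)


@dataclass
class MolecularEntity:
    atoms: list[ExpandedAtom]
    is_polymer: bool = False
    multiplicity: int = 1
    #: atoms of the unit cell claimed by this entity (defines the formula)
    cell_atoms: list[ExpandedAtom] = field(default_factory=list)

    def formula(self) -> dict[str, int]:
        source = self.cell_atoms or self.atoms
        counts: dict[str, int] = {}
        for atom in source:
            counts[atom.element] = counts.get(atom.element, 0) + 1
            if atom.attached_hydrogens:
                counts["H"] = counts.get("H", 0) + atom.attached_hydrogens
        return counts


@dataclass
class StoichiometricEnsemble:
    entities: list[MolecularEntity]
    space_group_number: int | None = None
    formula: dict[str, int] = field(default_factory=dict)
    contains_compositional_disorder: bool = False
    contains_partial_occupancy: bool = False
    entry_id: str | None = None

    @property
    def is_polymeric(self) -> bool:
        return any(e.is_polymer for e in self.entities)

    @property
    def is_sohncke(self) -> bool | None:
        if self.space_group_number is None:
            return None
        return self.space_group_number in SOHNCKE_GROUPS


# --------------------------------------------------------------------------
# Symmetry expansion
# --------------------------------------------------------------------------

def expand_to_unit_cell(desc: CrystalDescription,
                        merge_tol: float = DEFAULT_MERGE_TOL) -> list[ExpandedAtom]:
    """Image every site under every operator, merging special positions.

    Images of the *same* site closer than ``merge_tol`` (in Angstrom, over
    the shortest periodic image distance) to an earlier image are dropped.
    """
    if not desc.operators:
        raise ValueError("operator list is empty")
    mat = cartesian_matrix(desc.cell)
    shifts = np.array(list(product((-1, 0, 1), repeat=3)), dtype=float)
    atoms: list[ExpandedAtom] = []
    for site in desc.sites:
        seen_fracs: list[np.ndarray] = []
        for op_idx, op in enumerate(desc.operators):
            frac = apply_symop(op, site.frac, wrap=True)
            duplicate = False
            for prev in seen_fracs:
                delta = frac - prev
                cands = (delta + shifts) @ mat.T
                if float(np.min(np.linalg.norm(cands, axis=1))) < merge_tol:
                    duplicate = True
                    break
            if duplicate:
                continue
            seen_fracs.append(frac)
            cart = mat @ frac
            atoms.append(ExpandedAtom(
                site_ref=site.label, element=site.element,
                frac=tuple(frac), cart=tuple(cart), generating_op=op_idx,
                occupancy=site.occupancy,
                attached_hydrogens=site.attached_hydrogens,
                disorder_assembly=site.disorder_assembly,
                disorder_group=site.disorder_group))
    return atoms


# --------------------------------------------------------------------------
# Disorder resolution
# --------------------------------------------------------------------------

def _group_sort_key(group_name: str, members: list[AtomSite]):
    occ_sum = sum(s.occupancy for s in members)
    return (-occ_sum, -len(members), group_name)


def resolve_positional_disorder(
        sites: list[AtomSite], cell=None,
        position_tol: float = 0.5) -> tuple[list[AtomSite], dict[str, bool]]:
    """Retain one disorder group per assembly; detect compositional disorder.

    Selection within an assembly: (1) highest summed occupancy,
    (2) most atoms, (3) lexicographically lesser group name.  Sites whose
    alternative groups carry *different* elements at (nearly) the same
    position raise the compositional-disorder flag; such flags never remove
    the entry, they only mark it.
    """
    flags = {"compositional_disorder": False, "partial_occupancy": False}
    if any(s.occupancy < 1.0 for s in sites):
        flags["partial_occupancy"] = True

    assemblies: dict[str, dict[str, list[AtomSite]]] = {}
    plain: list[AtomSite] = []
    for site in sites:
        if site.disorder_group is None:
            plain.append(site)
        else:
            asm = site.disorder_assembly or "."
            assemblies.setdefault(asm, {}).setdefault(site.disorder_group, []).append(site)

    kept = list(plain)
    for asm, groups in sorted(assemblies.items()):
        # compositional disorder: different elements at ~equal positions in
        # alternative groups of the same assembly
        names = sorted(groups)
        for i, g1 in enumerate(names):
            for g2 in names[i + 1:]:
                for s1 in groups[g1]:
                    for s2 in groups[g2]:
                        if s1.element != s2.element and _sites_close(
                                s1, s2, cell, position_tol):
                            flags["compositional_disorder"] = True
        best = min(names, key=lambda g: _group_sort_key(g, groups[g]))
        kept.extend(groups[best])

    # compositional disorder can also be modelled without assemblies: two
    # partially occupied sites of different elements sharing one position
    for i, s1 in enumerate(plain):
        if s1.occupancy >= 1.0:
            continue
        for s2 in plain[i + 1:]:
            if (s2.occupancy < 1.0 and s1.element != s2.element
                    and s1.occupancy + s2.occupancy <= 1.0 + 1e-6
                    and _sites_close(s1, s2, cell, position_tol)):
                flags["compositional_disorder"] = True

    order = {id(s): k for k, s in enumerate(sites)}
    kept.sort(key=lambda s: order[id(s)])
    return kept, flags


def _sites_close(s1: AtomSite, s2: AtomSite, cell, tol: float) -> bool:
    d = np.array(s1.frac) - np.array(s2.frac)
    d -= np.round(d)
    if cell is not None:
        cart = cartesian_matrix(cell) @ d
        return float(np.linalg.norm(cart)) < tol
    return float(np.linalg.norm(d)) < tol


# --------------------------------------------------------------------------
# Bonding predicate
# --------------------------------------------------------------------------

def default_bond_fn(tolerance: float = DEFAULT_BOND_TOLERANCE,
                    max_bond_cutoff: float = DEFAULT_MAX_BOND_CUTOFF):
    """Distance criterion: bonded iff d <= min(rA + rB + tol, cutoff)."""
    radii = {sym: p.covalent_radius for sym, p in chem_tables.element_table().items()}

    def bond_fn(elem_a: str, cart_a, elem_b: str, cart_b) -> bool:
        d = math.dist(cart_a, cart_b)
        if d < 1e-6:
            return False
        limit = min(radii[elem_a] + radii[elem_b] + tolerance, max_bond_cutoff)
        return d <= limit

    return bond_fn


# --------------------------------------------------------------------------
# Entity growth across lattice translations
# --------------------------------------------------------------------------

def grow_entities(atoms: list[ExpandedAtom], cell, bond_fn=None,
                  max_polymer_atoms: int = DEFAULT_MAX_POLYMER_ATOMS
                  ) -> list[MolecularEntity]:
    """Trace covalently connected networks with periodic continuation.

    Breadth-first growth over lattice translations of the unit-cell atom
    list.  An entity is flagged as a polymer when growth reconnects to an
    image of an already-included atom under a different lattice shift;
    polymer growth halts at ``max_polymer_atoms``.
    """
    if bond_fn is None:
        bond_fn = default_bond_fn()
    mat = cartesian_matrix(cell)
    lattice = [mat @ np.array(s, dtype=float)
               for s in product((-1, 0, 1), repeat=3)]
    shift_vecs = list(product((-1, 0, 1), repeat=3))

    unassigned = {atom.key: atom for atom in atoms}
    entities: list[MolecularEntity] = []

    base_cart = {a.key: np.array(a.cart) for a in atoms}

    while unassigned:
        seed_key = min(unassigned, key=lambda k: (k[0], k[1]))
        seed = unassigned.pop(seed_key)
        members: dict[tuple, ExpandedAtom] = {seed.key: seed}
        site_op_shift: dict[tuple, tuple] = {seed.key[:2]: seed.lattice_shift}
        cell_atoms = [seed]
        is_polymer = False
        queue = deque([seed])
        while queue:
            current = queue.popleft()
            if is_polymer and len(members) >= max_polymer_atoms:
                break
            cur_cart = np.array(current.cart)
            for other in atoms:
                for shift, latt in zip(shift_vecs, lattice):
                    total_shift = tuple(
                        s + c for s, c in zip(shift, current.lattice_shift))
                    cand_cart = base_cart[other.key] + mat @ np.array(
                        total_shift, dtype=float)
                    if not bond_fn(current.element, cur_cart,
                                   other.element, cand_cart):
                        continue
                    key = (other.site_ref, other.generating_op, total_shift)
                    if key in members:
                        continue
                    so = key[:2]
                    if so in site_op_shift and site_op_shift[so] != total_shift:
                        # reconnected to a translated image of an atom
                        # already in this entity: periodic (polymeric)
                        is_polymer = True
                        if len(members) >= max_polymer_atoms:
                            continue
                    new_atom = replace(
                        other,
                        frac=tuple(np.array(other.frac)
                                   + np.array(total_shift, dtype=float)),
                        cart=tuple(cand_cart),
                        lattice_shift=total_shift)
                    members[key] = new_atom
                    site_op_shift.setdefault(so, total_shift)
                    if other.key in unassigned:
                        del unassigned[other.key]
                        cell_atoms.append(other)
                    queue.append(new_atom)
        entities.append(MolecularEntity(
            atoms=sorted(members.values(), key=lambda a: a.key),
            is_polymer=is_polymer, cell_atoms=cell_atoms))
    return entities


# --------------------------------------------------------------------------
# Ensemble assembly
# --------------------------------------------------------------------------

def _entity_signature(entity: MolecularEntity) -> tuple:
    return tuple(sorted((a.site_ref for a in entity.cell_atoms or entity.atoms)))


def build_ensemble(desc: CrystalDescription,
                   merge_tol: float = DEFAULT_MERGE_TOL,
                   bond_fn=None,
                   max_polymer_atoms: int = DEFAULT_MAX_POLYMER_ATOMS
                   ) -> StoichiometricEnsemble:
    """Full reconstruction: expand, resolve disorder, grow, reduce.

    Crystallographically independent entities are kept distinct even when
    chemically identical; symmetry copies of the same independent entity
    are reduced to one representative with a multiplicity, and the
    multiplicities are divided by their greatest common divisor so that the
    ensemble is the minimal stoichiometrically correct grouping.
    """
    sites, flags = resolve_positional_disorder(desc.sites, desc.cell)
    resolved = replace_sites(desc, sites)
    atoms = expand_to_unit_cell(resolved, merge_tol=merge_tol)
    entities = grow_entities(atoms, desc.cell, bond_fn=bond_fn,
                             max_polymer_atoms=max_polymer_atoms)

    groups: dict[tuple, list[MolecularEntity]] = {}
    for entity in entities:
        groups.setdefault(_entity_signature(entity), []).append(entity)
    representatives: list[MolecularEntity] = []
    multiplicities: list[int] = []
    for sig in sorted(groups):
        copies = groups[sig]
        rep = copies[0]
        rep.multiplicity = len(copies)
        representatives.append(rep)
        multiplicities.append(len(copies))
    g = math.gcd(*multiplicities) if multiplicities else 1
    formula: dict[str, int] = {}
    for rep in representatives:
        rep.multiplicity //= g
        for sym, cnt in rep.formula().items():
            formula[sym] = formula.get(sym, 0) + cnt * rep.multiplicity

    return StoichiometricEnsemble(
        entities=representatives,
        space_group_number=desc.space_group_number,
        formula=formula,
        contains_compositional_disorder=flags["compositional_disorder"],
        contains_partial_occupancy=flags["partial_occupancy"],
        entry_id=desc.entry_id,
    )


def replace_sites(desc: CrystalDescription,
                  sites: list[AtomSite]) -> CrystalDescription:
    return CrystalDescription(
        cell=desc.cell, operators=desc.operators, sites=sites,
        declared_formula=desc.declared_formula,
        space_group_number=desc.space_group_number,
        z_formula_units=desc.z_formula_units,
        doi=desc.doi, journal=desc.journal, year=desc.year,
        entry_id=desc.entry_id, markup_flags=set(desc.markup_flags))


def write_xyz(ensemble: StoichiometricEnsemble) -> str:
    """Debug dump of all entity atoms as extended XYZ text."""
    lines = []
    for idx, entity in enumerate(ensemble.entities):
        lines.append(str(len(entity.atoms)))
        lines.append(f"entity={idx} polymer={entity.is_polymer} "
                     f"multiplicity={entity.multiplicity}")
        for atom in entity.atoms:
            x, y, z = atom.cart
            lines.append(f"{atom.element:2s} {x:12.6f} {y:12.6f} {z:12.6f}")
    return "\n".join(lines) + "\n"
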
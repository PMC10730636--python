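"""Six-step chemical-structure assignment from 3D coordinates.

Pipeline (run by :func:`perceive`):

1. connectivity from interatomic distances and covalent radii;
2. preflight screen for fatal defects (steric clashes, exceeded valences);
3. zero-order bonds for every metal contact (hapticity falls out of the
   distance criterion: each coordinated atom within bonding distance of the
   metal gets its own zero-order bond);
4. unambiguous higher-order bonds (length + geometry admit a single order);
5. length-driven functional-group templates (azide, nitro, carboxylate,
   sulfonate, phosphate, nitrile, isocyanide);
6. Kekulé assignment of aromatic/resonant ring systems by perfect-matching
   search minimizing the summed squared length z-scores, avoiding opposite
   formal charges;
7. deviant higher-order bonds (length supports a higher order although the
   geometry is atypical);
8. formal charges (zero-order bonds are excluded from the bookkeeping;
   metal charges balance the ligand-system charges within the entity).

Once assigned, a structure is never normalized to a standard tautomeric or
resonance form.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import chem_tables
from .chem_tables import BondClassTable, by_symbol, default_bond_classes
from .ensemble import (DEFAULT_BOND_TOLERANCE, DEFAULT_MAX_BOND_CUTOFF,
                       StoichiometricEnsemble)

__all__ = [
    "Atom",
    "Bond",
    "ChemicalStructure",
    "PerceptionConfig",
    "PolymerInputError",
    "PreflightError",
    "Defect",
    "detect_connectivity",
    "preflight_screen",
    "assign_metal_bonds",
    "assign_unambiguous_bonds",
    "assign_functional_groups",
    "kekulize",
    "assign_deviant_bonds",
    "assign_formal_charges",
    "perceive",
]


class PolymerInputError(ValueError):
    """Polymeric ensembles are rejected with an explicit error."""


class PreflightError(ValueError):
    """Fatal geometry defects abort perception for the entry."""

    def __init__(self, defects):
        self.defects = list(defects)
        super().__init__("; ".join(d.message for d in self.defects))


@dataclass
class Defect:
    kind: str  # "bump" | "overvalence"
    atoms: tuple[int, ...]
    message: str


@dataclass
class Atom:
    element: str
    cart: tuple[float, float, float]
    formal_charge: int = 0
    attached_hydrogens: int = 0
    radical: bool = False
    entity: int = 0
    site_ref: str = ""
    occupancy: float = 1.0
    charge_fixed: bool = False  # set by templates / kekulization


@dataclass
class Bond:
    i: int
    j: int
    order: int = 1
    delocalized: bool = False
    length: float = 0.0
    order_fixed: bool = False

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


@dataclass
class ChemicalStructure:
    atoms: list[Atom]
    bonds: list[Bond]
    space_group_number: int | None = None
    entry_id: str | None = None
    issues: list = field(default_factory=list)

    def neighbors(self, idx: int, min_order: int = 0) -> list[int]:
        return [b.other(idx) for b in self.bonds
                if idx in (b.i, b.j) and b.order >= min_order]

    def bonds_of(self, idx: int) -> list[Bond]:
        return [b for b in self.bonds if idx in (b.i, b.j)]

    def bond_between(self, i: int, j: int) -> Bond | None:
        for b in self.bonds:
            if {b.i, b.j} == {i, j}:
                return b
        return None

    def covalent_order_sum(self, idx: int) -> int:
        """Sum of bond orders >= 1 plus attached hydrogens (order-0 bonds
        are excluded from all valence bookkeeping)."""
        return (sum(b.order for b in self.bonds_of(idx) if b.order >= 1)
                + self.atoms[idx].attached_hydrogens)

    def total_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)


@dataclass
class PerceptionConfig:
    tolerance: float = DEFAULT_BOND_TOLERANCE
    max_bond_cutoff: float = DEFAULT_MAX_BOND_CUTOFF
    clash_factor: float = 0.5
    planarity_angle_sum: float = 350.0  # degrees; sp2 gate
    linear_angle: float = 160.0         # degrees; sp gate
    torsion_threshold: float = 20.0     # degrees; double-bond twist gate
    sigma_window: float = 3.0           # |z| window for candidate orders
    max_atoms: int = 10000
    max_ring_size: int = 12


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------

def _angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    v1 = np.array(a) - np.array(b)
    v2 = np.array(c) - np.array(b)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _torsion(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees, folded into [0, 90]."""
    b0 = np.array(p1) - np.array(p0)
    b1 = np.array(p2) - np.array(p1)
    b2 = np.array(p3) - np.array(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return 0.0
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return min(ang, 180.0 - ang)


def heavy_neighbors(structure: ChemicalStructure, idx: int) -> list[int]:
    """Neighbours over order->=1 bonds (coordination contacts excluded)."""
    return structure.neighbors(idx, min_order=1)


def covalent_degree(structure: ChemicalStructure, idx: int) -> int:
    return (len(heavy_neighbors(structure, idx))
            + structure.atoms[idx].attached_hydrogens)


def angle_sum(structure: ChemicalStructure, idx: int) -> float | None:
    """Sum of the three bond angles at a 3-coordinate centre, else None."""
    nbrs = heavy_neighbors(structure, idx)
    if len(nbrs) != 3:
        return None
    a, b, c = (structure.atoms[n].cart for n in nbrs)
    center = structure.atoms[idx].cart
    return (_angle(a, center, b) + _angle(b, center, c) + _angle(a, center, c))


def is_sp2_compatible(structure: ChemicalStructure, idx: int,
                      cfg: PerceptionConfig) -> bool:
    """Planar 3-coordinate, 2-coordinate with an open site, or terminal."""
    atom = structure.atoms[idx]
    nbrs = heavy_neighbors(structure, idx)
    explicit = len(nbrs)
    degree = explicit + atom.attached_hydrogens
    if degree >= 4:
        return False
    if explicit == 3:
        s = angle_sum(structure, idx)
        return s is not None and s >= cfg.planarity_angle_sum
    # 0-2 explicit neighbours: geometry cannot veto planarity
    return True


def is_sp_compatible(structure: ChemicalStructure, idx: int,
                     cfg: PerceptionConfig) -> bool:
    atom = structure.atoms[idx]
    nbrs = heavy_neighbors(structure, idx)
    degree = len(nbrs) + atom.attached_hydrogens
    if degree > 2:
        return False
    if len(nbrs) == 2:
        a, b = (structure.atoms[n].cart for n in nbrs)
        return _angle(a, atom.cart, b) >= cfg.linear_angle
    return True


def double_bond_torsion(structure: ChemicalStructure, bond: Bond) -> float | None:
    """Largest substituent torsion across a bond, or None if unmeasurable."""
    ni = [n for n in heavy_neighbors(structure, bond.i) if n != bond.j]
    nj = [n for n in heavy_neighbors(structure, bond.j) if n != bond.i]
    if not ni or not nj:
        return None
    worst = 0.0
    for a in ni:
        for d in nj:
            worst = max(worst, _torsion(structure.atoms[a].cart,
                                        structure.atoms[bond.i].cart,
                                        structure.atoms[bond.j].cart,
                                        structure.atoms[d].cart))
    return worst


# --------------------------------------------------------------------------
# Step 1: connectivity
# --------------------------------------------------------------------------

def structure_from_ensemble(ens: StoichiometricEnsemble) -> ChemicalStructure:
    atoms: list[Atom] = []
    for ent_idx, entity in enumerate(ens.entities):
        for atom in entity.atoms:
            atoms.append(Atom(element=atom.element, cart=tuple(atom.cart),
                              attached_hydrogens=atom.attached_hydrogens,
                              entity=ent_idx, site_ref=atom.site_ref,
                              occupancy=atom.occupancy))
    return ChemicalStructure(atoms=atoms, bonds=[],
                             space_group_number=ens.space_group_number,
                             entry_id=ens.entry_id)


def detect_connectivity(structure: ChemicalStructure,
                        tolerance: float = DEFAULT_BOND_TOLERANCE,
                        max_bond_cutoff: float = DEFAULT_MAX_BOND_CUTOFF
                        ) -> list[Bond]:
    """All-pairs distance criterion; provisional order 1 for every bond.

    Atoms of different entities are never bonded (entities are the
    connected components the ensemble step produced).
    """
    bonds: list[Bond] = []
    atoms = structure.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if atoms[i].entity != atoms[j].entity:
                continue
            ri = by_symbol(atoms[i].element).covalent_radius
            rj = by_symbol(atoms[j].element).covalent_radius
            d = math.dist(atoms[i].cart, atoms[j].cart)
            if 1e-6 < d <= min(ri + rj + tolerance, max_bond_cutoff):
                bonds.append(Bond(i=i, j=j, order=1, length=d))
    structure.bonds = bonds
    return bonds


# --------------------------------------------------------------------------
# Step 2: preflight screen
# --------------------------------------------------------------------------

def preflight_screen(structure: ChemicalStructure,
                     cfg: PerceptionConfig | None = None) -> list[Defect]:
    """Report steric clashes and exceeded valences (fatal for the entry)."""
    cfg = cfg or PerceptionConfig()
    defects: list[Defect] = []
    atoms = structure.atoms
    for bond in structure.bonds:
        ri = by_symbol(atoms[bond.i].element).covalent_radius
        rj = by_symbol(atoms[bond.j].element).covalent_radius
        if bond.length < cfg.clash_factor * (ri + rj):
            defects.append(Defect(
                kind="bump", atoms=(bond.i, bond.j),
                message=(f"atomic bump between atoms {bond.i} and {bond.j} "
                         f"({bond.length:.2f} A)")))
    for idx, atom in enumerate(atoms):
        props = by_symbol(atom.element)
        if props.is_metal:
            continue  # coordination numbers of metals are unrestricted
        nonmetal_nbrs = [n for n in structure.neighbors(idx)
                         if not by_symbol(atoms[n].element).is_metal]
        degree = len(nonmetal_nbrs) + atom.attached_hydrogens
        if degree > props.max_valence:
            defects.append(Defect(
                kind="overvalence", atoms=(idx,),
                message=(f"atom {idx} ({atom.element}) has {degree} "
                         f"neighbours, exceeding max valence "
                         f"{props.max_valence}")))
    return defects


# --------------------------------------------------------------------------
# Step 3: metal coordination bonds
# --------------------------------------------------------------------------

def assign_metal_bonds(structure: ChemicalStructure) -> ChemicalStructure:
    """Every bond touching a metal becomes a zero-order coordination bond."""
    for bond in structure.bonds:
        if (by_symbol(structure.atoms[bond.i].element).is_metal
                or by_symbol(structure.atoms[bond.j].element).is_metal):
            bond.order = 0
            bond.order_fixed = True
    return structure


# --------------------------------------------------------------------------
# Step 4: unambiguous higher-order bonds
# --------------------------------------------------------------------------

def free_valence(structure: ChemicalStructure, idx: int) -> int:
    props = by_symbol(structure.atoms[idx].element)
    return props.max_valence - structure.covalent_order_sum(idx)


def _geometry_admits(structure: ChemicalStructure, bond: Bond, order: int,
                     cfg: PerceptionConfig) -> bool:
    if order == 1:
        return True
    if order == 2:
        return (is_sp2_compatible(structure, bond.i, cfg)
                and is_sp2_compatible(structure, bond.j, cfg))
    return (is_sp_compatible(structure, bond.i, cfg)
            and is_sp_compatible(structure, bond.j, cfg))


def assign_unambiguous_bonds(structure: ChemicalStructure,
                             classes: BondClassTable | None = None,
                             cfg: PerceptionConfig | None = None
                             ) -> ChemicalStructure:
    """Fix orders where length + endpoint geometry admit exactly one order."""
    classes = classes or default_bond_classes()
    cfg = cfg or PerceptionConfig()
    for bond in structure.bonds:
        if bond.order_fixed:
            continue
        za = by_symbol(structure.atoms[bond.i].element).Z
        zb = by_symbol(structure.atoms[bond.j].element).Z
        ranked = classes.rank_orders(za, zb, bond.length)
        if not ranked:
            continue  # no data: provisional single bond stands
        in_window = [(o, z) for o, z in ranked if z <= cfg.sigma_window]
        admissible = [
            (o, z) for o, z in in_window
            if _geometry_admits(structure, bond, o, cfg)
            and (o == 1 or (free_valence(structure, bond.i) >= o - 1
                            and free_valence(structure, bond.j) >= o - 1))
        ]
        if len(admissible) == 1:
            order = admissible[0][0]
            if order != bond.order:
                bond.order = order
            bond.order_fixed = True
    return structure


# --------------------------------------------------------------------------
# Step 5: functional-group templates
# --------------------------------------------------------------------------

def _set_charge(structure: ChemicalStructure, idx: int, charge: int):
    structure.atoms[idx].formal_charge = charge
    structure.atoms[idx].charge_fixed = True


def _fix_order(bond: Bond, order: int):
    bond.order = order
    bond.order_fixed = True


def _template_azide(structure: ChemicalStructure, classes: BondClassTable):
    """Linear N3 chain: double=double or single+triple by bond lengths."""
    zn = by_symbol("N").Z
    for c in range(len(structure.atoms)):
        if structure.atoms[c].element != "N":
            continue
        nbrs = [n for n in heavy_neighbors(structure, c)
                if structure.atoms[n].element == "N"]
        if len(nbrs) != 2:
            continue
        t1, t2 = sorted(nbrs)
        # terminal azide nitrogens: no further covalent neighbours
        if (len([n for n in heavy_neighbors(structure, t1) if n != c])
                or len([n for n in heavy_neighbors(structure, t2) if n != c])):
            continue
        if (structure.atoms[t1].attached_hydrogens
                or structure.atoms[t2].attached_hydrogens
                or structure.atoms[c].attached_hydrogens):
            continue
        b1 = structure.bond_between(c, t1)
        b2 = structure.bond_between(c, t2)
        dd = (classes.lookup(zn, zn, 2).zscore(b1.length) ** 2
              + classes.lookup(zn, zn, 2).zscore(b2.length) ** 2)
        # single+triple: try both orientations
        cls1 = classes.lookup(zn, zn, 1)
        cls3 = classes.lookup(zn, zn, 3)
        st_a = cls1.zscore(b1.length) ** 2 + cls3.zscore(b2.length) ** 2
        st_b = cls3.zscore(b1.length) ** 2 + cls1.zscore(b2.length) ** 2
        best_st = min(st_a, st_b)
        if dd <= best_st:
            _fix_order(b1, 2)
            _fix_order(b2, 2)
            _set_charge(structure, t1, -1)
            _set_charge(structure, c, 1)
            _set_charge(structure, t2, -1)
        else:
            single, triple = ((b1, b2) if st_a < st_b else (b2, b1))
            _fix_order(single, 1)
            _fix_order(triple, 3)
            _set_charge(structure, single.other(c), -2)
            _set_charge(structure, c, 1)
            _set_charge(structure, triple.other(c), 0)


def _terminal_oxygens(structure: ChemicalStructure, idx: int) -> list[int]:
    outs = []
    for n in heavy_neighbors(structure, idx):
        if (structure.atoms[n].element == "O"
                and len(heavy_neighbors(structure, n)) == 1):
            outs.append(n)
    return sorted(outs)


def _assign_oxo_pattern(structure: ChemicalStructure, center: int,
                        oxygens: list[int], n_double: int,
                        classes: BondClassTable):
    """Give the ``n_double`` shortest X-O bonds order 2; remaining terminal
    oxygens become single-bonded and, unless protonated, charged -1."""
    bonds = [(structure.bond_between(center, o), o) for o in oxygens]
    bonds.sort(key=lambda t: (t[0].length, t[1]))
    for k, (bond, o) in enumerate(bonds):
        if bond.order_fixed and bond.order >= 2 and k >= n_double:
            continue
        if k < n_double:
            _fix_order(bond, 2)
            _set_charge(structure, o, 0)
        else:
            _fix_order(bond, 1)
            if structure.atoms[o].attached_hydrogens == 0:
                _set_charge(structure, o, -1)


def _template_nitro(structure: ChemicalStructure, classes: BondClassTable):
    """R-NO2 / nitrate: one N=O plus N-O(-) with N(+)."""
    for idx, atom in enumerate(structure.atoms):
        if atom.element != "N":
            continue
        oxy = _terminal_oxygens(structure, idx)
        others = [n for n in heavy_neighbors(structure, idx) if n not in oxy]
        if len(oxy) == 2 and len(others) == 1:
            _assign_oxo_pattern(structure, idx, oxy, 1, classes)
            _set_charge(structure, idx, 1)
        elif len(oxy) == 3 and not others:  # nitrate anion
            _assign_oxo_pattern(structure, idx, oxy, 1, classes)
            _set_charge(structure, idx, 1)


def _template_carboxylate(structure: ChemicalStructure, classes: BondClassTable):
    """C bonded to two terminal O: C=O plus C-O(H) or C-O(-)."""
    for idx, atom in enumerate(structure.atoms):
        if atom.element != "C":
            continue
        oxy = _terminal_oxygens(structure, idx)
        if len(oxy) != 2:
            continue
        others = [n for n in heavy_neighbors(structure, idx) if n not in oxy]
        if len(others) + atom.attached_hydrogens != 1:
            continue
        _assign_oxo_pattern(structure, idx, oxy, 1, classes)


def _template_sulfonate(structure: ChemicalStructure, classes: BondClassTable):
    for idx, atom in enumerate(structure.atoms):
        if atom.element != "S":
            continue
        oxy = _terminal_oxygens(structure, idx)
        others = [n for n in heavy_neighbors(structure, idx) if n not in oxy]
        if len(oxy) == 3 and len(others) == 1:    # R-SO3
            _assign_oxo_pattern(structure, idx, oxy, 2, classes)
        elif len(oxy) == 4 and not others:        # sulfate
            _assign_oxo_pattern(structure, idx, oxy, 2, classes)


def _template_phosphate(structure: ChemicalStructure, classes: BondClassTable):
    for idx, atom in enumerate(structure.atoms):
        if atom.element != "P":
            continue
        oxy = _terminal_oxygens(structure, idx)
        others = [n for n in heavy_neighbors(structure, idx) if n not in oxy]
        if len(oxy) + len(others) == 4 and len(oxy) >= 2:
            _assign_oxo_pattern(structure, idx, oxy, 1, classes)


def _template_nitrile(structure: ChemicalStructure, classes: BondClassTable):
    """R-C#N and isocyanide R-N#C(-) by the triple-bond length class."""
    zc, zn = by_symbol("C").Z, by_symbol("N").Z
    cls3 = classes.lookup(zc, zn, 3)
    if cls3 is None:
        return
    for bond in structure.bonds:
        ei = structure.atoms[bond.i].element
        ej = structure.atoms[bond.j].element
        if {ei, ej} != {"C", "N"}:
            continue
        if abs(cls3.zscore(bond.length)) > 3.0:
            continue
        c_idx = bond.i if ei == "C" else bond.j
        n_idx = bond.other(c_idx)
        c_terminal = (len(heavy_neighbors(structure, c_idx)) == 1
                      and structure.atoms[c_idx].attached_hydrogens == 0)
        n_terminal = (len(heavy_neighbors(structure, n_idx)) == 1
                      and structure.atoms[n_idx].attached_hydrogens == 0)
        if n_terminal and not c_terminal:
            _fix_order(bond, 3)  # nitrile: neutral
        elif c_terminal and not n_terminal:
            _fix_order(bond, 3)  # isocyanide: R-N(+)#C(-)
            _set_charge(structure, n_idx, 1)
            _set_charge(structure, c_idx, -1)


_TEMPLATES = (
    _template_azide,
    _template_nitro,
    _template_carboxylate,
    _template_sulfonate,
    _template_phosphate,
    _template_nitrile,
)


def assign_functional_groups(structure: ChemicalStructure,
                             classes: BondClassTable | None = None
                             ) -> ChemicalStructure:
    classes = classes or default_bond_classes()
    for template in _TEMPLATES:
        template(structure, classes)
    return structure


# --------------------------------------------------------------------------
# Step 6: Kekulé / resonance assignment
# --------------------------------------------------------------------------

def _aromatic_extra_charge(structure: ChemicalStructure, ring: list[int]) -> int:
    """Charge needed to reach a 4k+2 pi count for a fully metal-coordinated
    ring (eta-coordination), assuming one pi electron per ring atom."""
    metal_partners = None
    for idx in ring:
        metals = {b.other(idx) for b in structure.bonds_of(idx)
                  if b.order == 0
                  and by_symbol(structure.atoms[b.other(idx)].element).is_metal}
        if not metals:
            return 0
        metal_partners = metals if metal_partners is None \
            else metal_partners & metals
        if not metal_partners:
            return 0
    n = len(ring)
    return -((2 - n) % 4)


def _ring_systems(structure: ChemicalStructure, cfg: PerceptionConfig
                  ) -> list[list[int]]:
    """Candidate aromatic ring systems: connected sets of cycle edges over
    pi-capable sp2 atoms whose bonds are still provisional.

    Bridges (edges in no cycle, e.g. a biphenyl link) are removed first so
    that each returned system is an independent Kekulé problem.
    """
    g = nx.Graph()
    for bond in structure.bonds:
        if bond.order_fixed or bond.order == 0:
            continue
        ei = structure.atoms[bond.i]
        ej = structure.atoms[bond.j]
        if not (by_symbol(ei.element).pi_capable
                and by_symbol(ej.element).pi_capable):
            continue
        if not (is_sp2_compatible(structure, bond.i, cfg)
                and is_sp2_compatible(structure, bond.j, cfg)):
            continue
        g.add_edge(bond.i, bond.j)
    g.remove_edges_from(list(nx.bridges(g)))
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    systems = []
    for comp in nx.connected_components(g):
        if 3 <= len(comp) <= 2 * cfg.max_ring_size:
            systems.append(sorted(comp))
    return systems


def _matching_cost(structure: ChemicalStructure, ring_edges, matching,
                   classes: BondClassTable) -> float:
    cost = 0.0
    for bond in ring_edges:
        za = by_symbol(structure.atoms[bond.i].element).Z
        zb = by_symbol(structure.atoms[bond.j].element).Z
        order = 2 if frozenset((bond.i, bond.j)) in matching else 1
        cls = classes.lookup(za, zb, order, (1, 1))
        if cls is None:
            cls = classes.lookup(za, zb, order)
        if cls is None:
            cost += 25.0  # no data: strongly discourage
        else:
            cost += cls.zscore(bond.length) ** 2
    return cost


def _charge_penalty(structure: ChemicalStructure, system: list[int],
                    ring_edges, matching, excluded) -> int:
    """Count of formal charges a candidate assignment would introduce.

    Penalized lexicographically before the length cost so that resonance
    forms avoiding (opposite) formal charges win whenever feasible.
    """
    penalty = 0
    matched_extra = {idx: 0 for idx in system}
    for bond in ring_edges:
        if frozenset((bond.i, bond.j)) in matching:
            matched_extra[bond.i] += 1
            matched_extra[bond.j] += 1
    for idx in system:
        props = by_symbol(structure.atoms[idx].element)
        total = structure.covalent_order_sum(idx) + matched_extra[idx]
        target = _closest_valence(props, total)
        if total > target:
            penalty += total - target
        elif idx in excluded and target - total > 0:
            penalty += target - total
    return penalty


def _enumerate_matchings(nodes: list[int], edges: list[tuple[int, int]]):
    """All perfect matchings of a small graph (rings <= 12 atoms)."""
    nodes = sorted(nodes)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def rec(remaining: frozenset, acc):
        if not remaining:
            yield frozenset(acc)
            return
        first = min(remaining)
        for nbr in sorted(adj[first]):
            if nbr in remaining:
                yield from rec(remaining - {first, nbr},
                               acc + [frozenset((first, nbr))])

    yield from rec(frozenset(nodes), [])


def kekulize(structure: ChemicalStructure,
             classes: BondClassTable | None = None,
             cfg: PerceptionConfig | None = None) -> ChemicalStructure:
    """Alternating single/double assignment per candidate ring system.

    The matching minimizing the summed squared z-scores of the assigned
    orders is chosen; atoms left unmatched (odd rings, or rings carrying a
    delocalized charge from eta-coordination to a metal) receive integer
    negative charges on valence-compatible positions.  All bonds of a
    successfully matched ring system are flagged delocalized.
    """
    classes = classes or default_bond_classes()
    cfg = cfg or PerceptionConfig()
    for system in _ring_systems(structure, cfg):
        system_set = set(system)
        ring_edges = [b for b in structure.bonds
                      if b.i in system_set and b.j in system_set
                      and not b.order_fixed and b.order != 0]
        if not ring_edges:
            continue
        edge_pairs = [(b.i, b.j) for b in ring_edges]
        extra = _aromatic_extra_charge(structure, system)
        n_excluded = abs(extra) if extra else (len(system) % 2)

        best = None  # (penalty, cost, excluded_tuple, matching_edges)
        if n_excluded == 0:
            candidates = [((), m) for m in
                          _enumerate_matchings(system, edge_pairs)]
        else:
            candidates = []
            for excluded in itertools.combinations(sorted(system), n_excluded):
                rest = [n for n in system if n not in excluded]
                if len(rest) % 2:
                    continue
                sub_edges = [(a, b) for a, b in edge_pairs
                             if a not in excluded and b not in excluded]
                for m in _enumerate_matchings(rest, sub_edges):
                    candidates.append((excluded, m))
        for excluded, matching in candidates:
            penalty = _charge_penalty(structure, system, ring_edges,
                                      matching, set(excluded))
            cost = _matching_cost(structure, ring_edges, matching, classes)
            key = (penalty, round(cost, 9), excluded,
                   tuple(sorted(tuple(sorted(e)) for e in matching)))
            if best is None or key < best:
                best = key
        if best is None:
            structure.issues.append(
                ("delocalization", tuple(system),
                 "no feasible Kekulé matching for ring system"))
            continue
        _, _, excluded, matching_edges = best
        matching = {frozenset(e) for e in matching_edges}
        for bond in ring_edges:
            bond.order = 2 if frozenset((bond.i, bond.j)) in matching else 1
            bond.order_fixed = True
            bond.delocalized = True
        for idx in excluded:
            props = by_symbol(structure.atoms[idx].element)
            total = structure.covalent_order_sum(idx)
            deficit = _closest_valence(props, total) - total
            _set_charge(structure, idx, -deficit if deficit > 0 else 0)
    return structure


# --------------------------------------------------------------------------
# Step 7: deviant higher-order bonds
# --------------------------------------------------------------------------

def assign_deviant_bonds(structure: ChemicalStructure,
                         classes: BondClassTable | None = None,
                         cfg: PerceptionConfig | None = None
                         ) -> ChemicalStructure:
    """Length-supported order upgrades that ignore the geometry gates.

    Never overrides orders fixed by earlier steps.
    """
    classes = classes or default_bond_classes()
    cfg = cfg or PerceptionConfig()
    for bond in structure.bonds:
        if bond.order_fixed:
            continue
        za = by_symbol(structure.atoms[bond.i].element).Z
        zb = by_symbol(structure.atoms[bond.j].element).Z
        ranked = classes.rank_orders(za, zb, bond.length)
        if not ranked:
            continue
        order, z = ranked[0]
        if (order > 1 and z <= cfg.sigma_window
                and free_valence(structure, bond.i) >= order - 1
                and free_valence(structure, bond.j) >= order - 1):
            bond.order = order
            bond.order_fixed = True
    return structure


# --------------------------------------------------------------------------
# Step 8: formal charges
# --------------------------------------------------------------------------

#: Non-metals that accept an anionic charge equal to their valence deficit.
_ELECTRONEGATIVE_ANIONS = frozenset({"O", "S", "Se", "Te",
                                     "F", "Cl", "Br", "I", "At", "H"})


def _closest_valence(props, total: int) -> int:
    """Smallest allowed valence >= total, else the maximum."""
    for v in sorted(props.max_valences):
        if total <= v:
            return v
    return props.max_valence


def assign_formal_charges(structure: ChemicalStructure) -> ChemicalStructure:
    """Valence bookkeeping over order>=1 bonds; coordination bonds ignored.

    Metals receive the charge that balances the summed ligand-system
    charges within their entity, restricted to the enumerated oxidation
    states (0 is always admissible); an inadmissible requirement is
    recorded as a charge issue.
    """
    atoms = structure.atoms
    for idx, atom in enumerate(atoms):
        props = by_symbol(atom.element)
        if props.is_metal or atom.charge_fixed:
            continue
        total = structure.covalent_order_sum(idx)
        target = _closest_valence(props, total)
        if total > target:
            atom.formal_charge = total - target  # hypervalent: cationic
            continue
        deficit = target - total
        if deficit == 0:
            atom.formal_charge = 0
            continue
        has_coordination = any(b.order == 0 for b in structure.bonds_of(idx))
        if has_coordination or atom.element in _ELECTRONEGATIVE_ANIONS:
            atom.formal_charge = -deficit
        elif deficit % 2 == 1:
            atom.radical = True
        # even deficit on an electropositive atom: lone pair (carbene-like),
        # charge stays 0

    # metal charges balance each entity
    entities: dict[int, list[int]] = {}
    for idx, atom in enumerate(atoms):
        entities.setdefault(atom.entity, []).append(idx)
    for members in entities.values():
        metals = [i for i in members if by_symbol(atoms[i].element).is_metal]
        if not metals:
            continue
        ligand_charge = sum(atoms[i].formal_charge for i in members
                            if i not in metals)
        required = -ligand_charge
        _distribute_metal_charge(structure, metals, required)
    return structure


def _distribute_metal_charge(structure: ChemicalStructure,
                             metals: list[int], required: int):
    atoms = structure.atoms
    if len(metals) == 1:
        idx = metals[0]
        states = set(by_symbol(atoms[idx].element).oxidation_states) | {0}
        atoms[idx].formal_charge = required
        if required not in states:
            structure.issues.append(
                ("atom_charge", (idx,),
                 f"metal {atoms[idx].element} requires charge {required} "
                 f"outside its enumerated oxidation states"))
        return
    # several metals: assign greedily, preferring even splits of admissible
    # states; remainder goes to the first metal
    share = required // len(metals)
    rem = required - share * len(metals)
    for k, idx in enumerate(sorted(metals)):
        charge = share + (rem if k == 0 else 0)
        states = set(by_symbol(atoms[idx].element).oxidation_states) | {0}
        atoms[idx].formal_charge = charge
        if charge not in states:
            structure.issues.append(
                ("atom_charge", (idx,),
                 f"metal {atoms[idx].element} requires charge {charge} "
                 f"outside its enumerated oxidation states"))


# --------------------------------------------------------------------------
# Driver
# --------------------------------------------------------------------------

def perceive(ens: StoichiometricEnsemble,
             classes: BondClassTable | None = None,
             config: PerceptionConfig | None = None) -> ChemicalStructure:
    """Run the full assignment pipeline on a non-polymeric ensemble."""
    cfg = config or PerceptionConfig()
    classes = classes or default_bond_classes()
    if ens.is_polymeric:
        raise PolymerInputError(
            "input describes a polymeric molecular entity; polymers are "
            "not supported and the entry is rejected")
    structure = structure_from_ensemble(ens)
    if len(structure.atoms) > cfg.max_atoms:
        raise PreflightError([Defect(
            kind="capacity", atoms=(),
            message=f"structure exceeds the configured atom limit "
                    f"({len(structure.atoms)} > {cfg.max_atoms})")])
    detect_connectivity(structure, cfg.tolerance, cfg.max_bond_cutoff)
    assign_metal_bonds(structure)
    defects = preflight_screen(structure, cfg)
    if defects:
        raise PreflightError(defects)
    assign_unambiguous_bonds(structure, classes, cfg)
    assign_functional_groups(structure, classes)
    kekulize(structure, classes, cfg)
    assign_deviant_bonds(structure, classes, cfg)
    assign_formal_charges(structure)
    return structure
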
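"""Molecular-geometry checks and entry-level data-quality tests.

Structure checks (each produces :class:`Issue` records, never removes
anything): pi-electron count, bond geometry, bond length (3-sigma rule),
radicals, atom charges, ensemble charge sum.

Entry tests (each a pass/fail criterion in :class:`EntryVerdict`):
chemical structure, chemical formula compatibility, data provenance,
compositional disorder, maintainer markup, manual review.  Failing entries
are marked, never dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import chem_tables
from .chem_tables import BondClassTable, by_symbol, default_bond_classes
from .cif_io import CrystalDescription
from .ensemble import StoichiometricEnsemble
from .perception import (ChemicalStructure, PerceptionConfig, angle_sum,
                         covalent_degree, double_bond_torsion,
                         heavy_neighbors, _angle)

__all__ = [
    "ValidationConfig",
    "Issue",
    "EntryVerdict",
    "check_pi_count",
    "check_bond_geometry",
    "check_bond_length",
    "check_radicals",
    "check_atom_charges",
    "check_ensemble_charge",
    "validate_structure",
    "formula_compatible",
    "judge_entry",
]

ISSUE_CATEGORIES = ("pi_count", "bond_geometry", "bond_length", "radical",
                    "atom_charge", "ensemble_charge", "delocalization")


@dataclass(frozen=True)
class Issue:
    category: str
    atoms: tuple[int, ...]
    message: str

    def __post_init__(self):
        if self.category not in ISSUE_CATEGORIES:
            raise ValueError(f"unknown issue category: {self.category!r}")


@dataclass
class ValidationConfig:
    sigma_threshold: float = 3.0
    planarity_angle_sum: float = 350.0
    torsion_threshold: float = 20.0
    linear_angle: float = 160.0
    check_pi: bool = True
    check_geometry: bool = True
    check_length: bool = True
    check_radical: bool = True
    check_charge: bool = True
    check_ensemble: bool = True

    def __post_init__(self):
        if self.sigma_threshold <= 0:
            raise ValueError("sigma_threshold must be > 0")


# --------------------------------------------------------------------------
# pi-electron count
# --------------------------------------------------------------------------

def _factual_pi(structure: ChemicalStructure, idx: int) -> int:
    """Double bond -> 1 pi electron, triple -> 2; any delocalized
    participation counts as a single pi electron in total."""
    bonds = structure.bonds_of(idx)
    if any(b.delocalized for b in bonds):
        return 1
    total = 0
    for b in bonds:
        if b.order == 2:
            total += 1
        elif b.order == 3:
            total += 2
    return total


def _expected_pi(structure: ChemicalStructure, idx: int,
                 cfg: ValidationConfig) -> int | None:
    """Expected pi count from species + geometry; None when undecidable."""
    degree = covalent_degree(structure, idx)
    explicit = heavy_neighbors(structure, idx)
    if degree >= 4:
        return 0
    if len(explicit) == 3:
        s = angle_sum(structure, idx)
        if s is None:
            return None
        return 1 if s >= cfg.planarity_angle_sum else 0
    if len(explicit) == 2 and degree == 2:
        a, b = (structure.atoms[n].cart for n in explicit)
        ang = _angle(a, structure.atoms[idx].cart, b)
        if ang >= cfg.linear_angle:
            return 2
        return None  # bent 2-coordinate: sp2 vs sp3 not decidable from angle
    return None  # terminal or H-only environments carry no angle signal


def check_pi_count(structure: ChemicalStructure,
                   cfg: ValidationConfig | None = None) -> list[Issue]:
    cfg = cfg or ValidationConfig()
    issues = []
    for idx, atom in enumerate(structure.atoms):
        if not by_symbol(atom.element).pi_capable:
            continue
        expected = _expected_pi(structure, idx, cfg)
        if expected is None:
            continue
        factual = _factual_pi(structure, idx)
        if factual != expected:
            issues.append(Issue(
                "pi_count", (idx,),
                f"atom {idx} ({atom.element}): factual pi count {factual} "
                f"vs expected {expected}"))
    return issues


# --------------------------------------------------------------------------
# bond geometry
# --------------------------------------------------------------------------

def check_bond_geometry(structure: ChemicalStructure,
                        cfg: ValidationConfig | None = None) -> list[Issue]:
    """Higher-order bonds must be planar/linear; lengths play no role."""
    cfg = cfg or ValidationConfig()
    issues = []
    for bond in structure.bonds:
        if bond.order < 2:
            continue
        if bond.order == 2:
            for idx in (bond.i, bond.j):
                s = angle_sum(structure, idx)
                if s is not None and s < cfg.planarity_angle_sum:
                    issues.append(Issue(
                        "bond_geometry", (bond.i, bond.j),
                        f"double bond {bond.i}-{bond.j}: pyramidal centre "
                        f"at atom {idx} (angle sum {s:.1f} deg)"))
            twist = double_bond_torsion(structure, bond)
            if twist is not None and twist > cfg.torsion_threshold:
                issues.append(Issue(
                    "bond_geometry", (bond.i, bond.j),
                    f"double bond {bond.i}-{bond.j}: torsion "
                    f"{twist:.1f} deg exceeds {cfg.torsion_threshold} deg"))
        else:  # triple
            for idx in (bond.i, bond.j):
                nbrs = heavy_neighbors(structure, idx)
                if len(nbrs) == 2:
                    a, b = (structure.atoms[n].cart for n in nbrs)
                    ang = _angle(a, structure.atoms[idx].cart, b)
                    if ang < cfg.linear_angle:
                        issues.append(Issue(
                            "bond_geometry", (bond.i, bond.j),
                            f"triple bond {bond.i}-{bond.j}: non-linear "
                            f"centre at atom {idx} ({ang:.1f} deg)"))
    return issues


# --------------------------------------------------------------------------
# bond length (3-sigma rule)
# --------------------------------------------------------------------------

def check_bond_length(structure: ChemicalStructure,
                      classes: BondClassTable | None = None,
                      cfg: ValidationConfig | None = None) -> list[Issue]:
    """Flag a bond iff |z| exceeds the threshold for its assigned class AND
    some alternative order has a smaller |z|."""
    classes = classes or default_bond_classes()
    cfg = cfg or ValidationConfig()
    issues = []
    for bond in structure.bonds:
        if bond.order == 0:
            continue
        za = by_symbol(structure.atoms[bond.i].element).Z
        zb = by_symbol(structure.atoms[bond.j].element).Z
        context = (_factual_pi(structure, bond.i),
                   _factual_pi(structure, bond.j))
        ranked = classes.rank_orders(za, zb, bond.length, context)
        own = dict(ranked).get(bond.order)
        if own is None or own <= cfg.sigma_threshold + 1e-9:
            continue
        better = [o for o, z in ranked if o != bond.order and z < own]
        if better:
            issues.append(Issue(
                "bond_length", (bond.i, bond.j),
                f"bond {bond.i}-{bond.j} order {bond.order}: |z|={own:.2f} "
                f"exceeds {cfg.sigma_threshold} and order {better[0]} fits "
                f"better"))
    return issues


# --------------------------------------------------------------------------
# radicals / charges
# --------------------------------------------------------------------------

def check_radicals(structure: ChemicalStructure) -> list[Issue]:
    return [Issue("radical", (idx,),
                  f"atom {idx} ({atom.element}) is a radical")
            for idx, atom in enumerate(structure.atoms) if atom.radical]


def check_atom_charges(structure: ChemicalStructure) -> list[Issue]:
    """Metal charges must be enumerated oxidation states (or 0); non-metal
    charges must belong to the valence-derived allowed set."""
    issues = []
    for idx, atom in enumerate(structure.atoms):
        props = by_symbol(atom.element)
        q = atom.formal_charge
        if props.is_metal:
            allowed = set(props.oxidation_states) | {0}
        else:
            allowed = set(props.allowed_charges)
        if q not in allowed:
            issues.append(Issue(
                "atom_charge", (idx,),
                f"atom {idx} ({atom.element}) charge {q:+d} outside the "
                f"allowed set"))
    return issues


def check_ensemble_charge(structure: ChemicalStructure) -> list[Issue]:
    total = structure.total_charge()
    if total != 0:
        return [Issue("ensemble_charge", (),
                      f"ensemble formal charge sum is {total:+d}, not 0")]
    return []


def validate_structure(structure: ChemicalStructure,
                       classes: BondClassTable | None = None,
                       cfg: ValidationConfig | None = None) -> list[Issue]:
    """Run all six structure checks plus any issues perception recorded."""
    cfg = cfg or ValidationConfig()
    issues: list[Issue] = []
    for rec in structure.issues:  # perception-recorded problems
        if isinstance(rec, Issue):
            issues.append(rec)
        else:
            cat, atoms, msg = rec
            issues.append(Issue(cat, tuple(atoms), msg))
    if cfg.check_pi:
        issues += check_pi_count(structure, cfg)
    if cfg.check_geometry:
        issues += check_bond_geometry(structure, cfg)
    if cfg.check_length:
        issues += check_bond_length(structure, classes, cfg)
    if cfg.check_radical:
        issues += check_radicals(structure)
    if cfg.check_charge:
        issues += check_atom_charges(structure)
    if cfg.check_ensemble:
        issues += check_ensemble_charge(structure)
    return issues


# --------------------------------------------------------------------------
# Entry-level criteria
# --------------------------------------------------------------------------

CRITERIA = ("chemical_structure", "chemical_formula", "data_provenance",
            "compositional_disorder", "cod_markup", "manual_review")


@dataclass
class EntryVerdict:
    criteria: dict[str, bool] = field(default_factory=dict)

    @property
    def overall_valid(self) -> bool:
        return all(self.criteria.get(c, True) for c in CRITERIA)

    def failed(self) -> list[str]:
        return [c for c in CRITERIA if not self.criteria.get(c, True)]


def formula_compatible(declared: dict[str, int],
                       computed: dict[str, int]) -> bool:
    """True iff computed = k x declared for a single positive integer k."""
    if not declared or not computed:
        return False
    if set(declared) != set(computed):
        return False
    k = None
    for elem, dcount in declared.items():
        ccount = computed[elem]
        if dcount <= 0 or ccount <= 0 or ccount % dcount:
            return False
        ratio = ccount // dcount
        if k is None:
            k = ratio
        elif ratio != k:
            return False
    return k is not None and k >= 1


def judge_entry(issues: list[Issue], desc: CrystalDescription,
                ens: StoichiometricEnsemble) -> EntryVerdict:
    """Apply the six entry-level data-quality criteria (mark, never drop)."""
    verdict = EntryVerdict()
    verdict.criteria["chemical_structure"] = not issues
    if desc.declared_formula:
        verdict.criteria["chemical_formula"] = formula_compatible(
            desc.declared_formula, ens.formula)
    else:
        verdict.criteria["chemical_formula"] = False
    has_doi = bool(desc.doi)
    has_citation = bool(desc.journal and desc.year)
    verdict.criteria["data_provenance"] = has_doi or has_citation
    verdict.criteria["compositional_disorder"] = \
        not ens.contains_compositional_disorder
    verdict.criteria["cod_markup"] = not (
        desc.markup_flags & {"duplicate", "suboptimal", "theoretical"})
    verdict.criteria["manual_review"] = "manual-exclusion" not in desc.markup_flags
    return verdict
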
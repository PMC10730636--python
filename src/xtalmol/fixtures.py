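"""Synthetic crystal-structure fixtures.

Deterministic, seedless generators producing idealized gas-phase-like
molecules in large P1 boxes (plus deliberately defective structures) both
as in-memory crystal descriptions and as CIF text.  Each generator stands
in for a class of real database entries: the metallocene convention, the
length-driven azide duality, ionic contacts, rock-salt stoichiometry, a
1-D polymer chain, and disorder/defect scenarios.
"""

from __future__ import annotations

import math

import numpy as np

from .cif_io import (AtomSite, CrystalDescription, UnitCell, parse_symop,
                     read_cif, IDENTITY_OP)

__all__ = [
    "make_benzene",
    "make_ferrocene",
    "make_azide",
    "make_water",
    "make_nacl_contact",
    "make_rock_salt",
    "make_defect",
    "make_two_waters",
    "make_carbonyl",
    "make_chain",
    "to_cif",
    "all_fixtures",
]

CC_AROMATIC = 1.39
CC_CP = 1.43
CH = 1.08
FE_CENTROID = 1.66


def _p1_description(sites, box: float, formula=None, **meta) -> CrystalDescription:
    cell = UnitCell(box, box, box)
    defaults = dict(doi="10.0000/xtalmol.fixture", journal="Fixture Journal",
                    year="2024", space_group_number=1)
    defaults.update(meta)
    return CrystalDescription(cell=cell, operators=[IDENTITY_OP],
                              sites=sites, declared_formula=formula or {},
                              **defaults)


def _centered_sites(positions, box: float):
    """Cartesian positions (centered on origin) -> fractional in a cubic box."""
    out = []
    center = box / 2.0
    for label, element, xyz, extra in positions:
        frac = tuple((c + center) / box for c in xyz)
        out.append(AtomSite(label=label, element=element, frac=frac, **extra))
    return out


def make_benzene(cell_padding: float = 6.0) -> CrystalDescription:
    """Planar C6H6 ring (C-C 1.39, C-H 1.08) isolated in a P1 box."""
    box = 2 * (CC_AROMATIC + CH) + 2 * cell_padding
    r_c = CC_AROMATIC / (2 * math.sin(math.pi / 6))
    positions = []
    for k in range(6):
        ang = 2 * math.pi * k / 6
        c = (r_c * math.cos(ang), r_c * math.sin(ang), 0.0)
        h = ((r_c + CH) * math.cos(ang), (r_c + CH) * math.sin(ang), 0.0)
        positions.append((f"C{k + 1}", "C", c, {}))
        positions.append((f"H{k + 1}", "H", h, {}))
    return _p1_description(_centered_sites(positions, box), box,
                           formula={"C": 6, "H": 6}, entry_id="fix-benzene")


def make_ferrocene() -> CrystalDescription:
    """Eclipsed D5h ferrocene: two parallel C5H5 rings around one Fe."""
    box = 16.0
    r_ring = CC_CP / (2 * math.sin(math.pi / 5))
    positions = [("Fe1", "Fe", (0.0, 0.0, 0.0), {})]
    for ring, z in ((1, FE_CENTROID), (2, -FE_CENTROID)):
        for k in range(5):
            ang = 2 * math.pi * k / 5
            c = (r_ring * math.cos(ang), r_ring * math.sin(ang), z)
            h = ((r_ring + CH) * math.cos(ang), (r_ring + CH) * math.sin(ang), z)
            positions.append((f"C{ring}{k + 1}", "C", c, {}))
            positions.append((f"H{ring}{k + 1}", "H", h, {}))
    return _p1_description(_centered_sites(positions, box), box,
                           formula={"C": 10, "H": 10, "Fe": 1},
                           entry_id="fix-ferrocene")


def make_azide(d1: float = 1.24, d2: float = 1.24,
               counterion: str = "Na") -> CrystalDescription:
    """Linear N3 anion (N-N distances d1, d2) plus a coordinated metal.

    The counterion sits along the chain axis at coordination distance from
    the d1-side terminal nitrogen.
    """
    box = 14.0
    positions = [
        ("N1", "N", (-d1, 0.0, 0.0), {}),
        ("N2", "N", (0.0, 0.0, 0.0), {}),
        ("N3", "N", (d2, 0.0, 0.0), {}),
        (f"{counterion}1", counterion, (-d1 - 2.35, 0.0, 0.0), {}),
    ]
    return _p1_description(_centered_sites(positions, box), box,
                           formula={"N": 3, counterion: 1},
                           entry_id="fix-azide")


def make_water() -> CrystalDescription:
    box = 10.0
    ang = math.radians(104.5) / 2
    d = 0.96
    positions = [
        ("O1", "O", (0.0, 0.0, 0.0), {}),
        ("H1", "H", (d * math.sin(ang), d * math.cos(ang), 0.0), {}),
        ("H2", "H", (-d * math.sin(ang), d * math.cos(ang), 0.0), {}),
    ]
    return _p1_description(_centered_sites(positions, box), box,
                           formula={"O": 1, "H": 2}, entry_id="fix-water")


def make_two_waters() -> CrystalDescription:
    """Two crystallographically independent, chemically identical waters."""
    box = 14.0
    ang = math.radians(104.5) / 2
    d = 0.96
    positions = []
    for k, offset in enumerate(((-3.5, 0.0, 0.0), (3.5, 0.5, 0.0))):
        ox, oy, oz = offset
        positions += [
            (f"O{k + 1}", "O", (ox, oy, oz), {}),
            (f"H{2 * k + 1}", "H",
             (ox + d * math.sin(ang), oy + d * math.cos(ang), oz), {}),
            (f"H{2 * k + 2}", "H",
             (ox - d * math.sin(ang), oy + d * math.cos(ang), oz), {}),
        ]
    return _p1_description(_centered_sites(positions, box), box,
                           formula={"O": 2, "H": 4}, entry_id="fix-2waters")


def make_nacl_contact(distance: float = 2.8) -> CrystalDescription:
    """An isolated Na...Cl ion pair at coordination distance."""
    box = 12.0
    positions = [
        ("Na1", "Na", (0.0, 0.0, 0.0), {}),
        ("Cl1", "Cl", (distance, 0.0, 0.0), {}),
    ]
    return _p1_description(_centered_sites(positions, box), box,
                           formula={"Na": 1, "Cl": 1}, entry_id="fix-nacl")


def make_rock_salt() -> CrystalDescription:
    """Conventional NaCl cell in P1 (4 Na + 4 Cl): an infinite ionic network."""
    a = 5.64
    cell = UnitCell(a, a, a)
    na_fracs = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    cl_fracs = [(0.5, 0, 0), (0, 0.5, 0), (0, 0, 0.5), (0.5, 0.5, 0.5)]
    sites = [AtomSite(label=f"Na{k + 1}", element="Na", frac=f)
             for k, f in enumerate(na_fracs)]
    sites += [AtomSite(label=f"Cl{k + 1}", element="Cl", frac=f)
              for k, f in enumerate(cl_fracs)]
    return CrystalDescription(cell=cell, operators=[IDENTITY_OP], sites=sites,
                              declared_formula={"Na": 1, "Cl": 1},
                              space_group_number=1,
                              doi="10.0000/xtalmol.fixture",
                              entry_id="fix-rocksalt")


def make_carbonyl(d: float = 1.22) -> CrystalDescription:
    """H2C=O with the C-O distance as given."""
    box = 10.0
    ang = math.radians(120.0)
    ch = 1.09
    positions = [
        ("C1", "C", (0.0, 0.0, 0.0), {}),
        ("O1", "O", (d, 0.0, 0.0), {}),
        ("H1", "H", (ch * math.cos(ang), ch * math.sin(ang), 0.0), {}),
        ("H2", "H", (ch * math.cos(ang), -ch * math.sin(ang), 0.0), {}),
    ]
    return _p1_description(_centered_sites(positions, box), box,
                           formula={"C": 1, "H": 2, "O": 1},
                           entry_id="fix-carbonyl")


def make_chain(n_atoms: int = 1, spacing: float = 1.54) -> CrystalDescription:
    """1-D carbon chain continuous across the cell boundary (a polymer)."""
    a = n_atoms * spacing
    cell = UnitCell(a, 15.0, 15.0)
    sites = []
    for k in range(n_atoms):
        sites.append(AtomSite(label=f"C{k + 1}", element="C",
                              frac=((k * spacing) / a, 0.5, 0.5),
                              attached_hydrogens=2))
    return CrystalDescription(cell=cell, operators=[IDENTITY_OP], sites=sites,
                              declared_formula={"C": n_atoms, "H": 2 * n_atoms},
                              space_group_number=1,
                              doi="10.0000/xtalmol.fixture",
                              entry_id="fix-chain")


def make_defect(kind: str, group_occupancies=(0.5, 0.5),
                group_names=("1", "2")) -> CrystalDescription:
    """Deliberately defective structures.

    kind: ``clash`` (two C at 0.5 A), ``overvalence`` (C with 5 C
    neighbours), ``polymer`` (continuous 1-D chain), ``disorder``
    (one assembly, two alternative groups) or ``compositional``
    (Fe/Co 1:1 shared site).
    """
    if kind == "clash":
        box = 10.0
        positions = [("C1", "C", (0.0, 0.0, 0.0), {}),
                     ("C2", "C", (0.5, 0.0, 0.0), {})]
        return _p1_description(_centered_sites(positions, box), box,
                               formula={"C": 2}, entry_id="fix-clash")
    if kind == "overvalence":
        box = 12.0
        d = 1.54
        positions = [("C0", "C", (0.0, 0.0, 0.0), {})]
        directions = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1)]
        for k, (x, y, z) in enumerate(directions):
            positions.append((f"C{k + 1}", "C", (d * x, d * y, d * z),
                              {"attached_hydrogens": 3}))
        return _p1_description(_centered_sites(positions, box), box,
                               formula={"C": 6, "H": 15},
                               entry_id="fix-overvalence")
    if kind == "polymer":
        return make_chain()
    if kind == "disorder":
        box = 12.0
        occ1, occ2 = group_occupancies
        g1, g2 = group_names
        positions = [
            ("C1", "C", (0.0, 0.0, 0.0), {"attached_hydrogens": 3}),
            ("O1A", "O", (1.42, 0.0, 0.0),
             {"occupancy": occ1, "disorder_assembly": "A",
              "disorder_group": g1, "attached_hydrogens": 1}),
            ("O1B", "O", (0.30, 1.39, 0.0),
             {"occupancy": occ2, "disorder_assembly": "A",
              "disorder_group": g2, "attached_hydrogens": 1}),
        ]
        return _p1_description(_centered_sites(positions, box), box,
                               formula={"C": 1, "O": 1, "H": 4},
                               entry_id="fix-disorder")
    if kind == "compositional":
        box = 12.0
        positions = [
            ("Fe1", "Fe", (0.0, 0.0, 0.0),
             {"occupancy": 0.5, "disorder_assembly": "A",
              "disorder_group": "1"}),
            ("Co1", "Co", (0.0, 0.0, 0.0),
             {"occupancy": 0.5, "disorder_assembly": "A",
              "disorder_group": "2"}),
            ("Cl1", "Cl", (2.3, 0.0, 0.0), {}),
            ("Cl2", "Cl", (-2.3, 0.0, 0.0), {}),
        ]
        return _p1_description(_centered_sites(positions, box), box,
                               formula={"Fe": 1, "Cl": 2},
                               entry_id="fix-compositional")
    raise ValueError(f"unknown defect kind: {kind!r}")


# --------------------------------------------------------------------------
# CIF emission
# --------------------------------------------------------------------------

def to_cif(desc: CrystalDescription, name: str = "fixture") -> str:
    """Serialize a description in the CIF dialect read_cif understands."""
    lines = [f"data_{desc.entry_id or name}"]
    if desc.entry_id:
        lines.append(f"_cod_database_code {desc.entry_id}")
    lines.append(f"_cell_length_a {desc.cell.a:.6f}")
    lines.append(f"_cell_length_b {desc.cell.b:.6f}")
    lines.append(f"_cell_length_c {desc.cell.c:.6f}")
    lines.append(f"_cell_angle_alpha {desc.cell.alpha:.4f}")
    lines.append(f"_cell_angle_beta {desc.cell.beta:.4f}")
    lines.append(f"_cell_angle_gamma {desc.cell.gamma:.4f}")
    if desc.space_group_number is not None:
        lines.append(f"_space_group_IT_number {desc.space_group_number}")
    if desc.declared_formula:
        formula = " ".join(f"{el}{n}" for el, n
                           in sorted(desc.declared_formula.items()))
        lines.append(f"_chemical_formula_sum '{formula}'")
    if desc.doi:
        lines.append(f"_journal_paper_doi {desc.doi}")
    if desc.journal:
        lines.append(f"_journal_name_full '{desc.journal}'")
    if desc.year:
        lines.append(f"_journal_year {desc.year}")
    lines.append("loop_")
    lines.append("_space_group_symop_operation_xyz")
    from .cif_io import format_symop
    for op in desc.operators:
        lines.append(f"'{format_symop(op)}'")
    lines.append("loop_")
    lines.append("_atom_site_label")
    lines.append("_atom_site_type_symbol")
    lines.append("_atom_site_fract_x")
    lines.append("_atom_site_fract_y")
    lines.append("_atom_site_fract_z")
    lines.append("_atom_site_occupancy")
    lines.append("_atom_site_attached_hydrogens")
    lines.append("_atom_site_disorder_assembly")
    lines.append("_atom_site_disorder_group")
    for s in desc.sites:
        asm = s.disorder_assembly or "."
        grp = s.disorder_group or "."
        lines.append(
            f"{s.label} {s.element} {s.frac[0]:.8f} {s.frac[1]:.8f} "
            f"{s.frac[2]:.8f} {s.occupancy:.4f} {s.attached_hydrogens} "
            f"{asm} {grp}")
    return "\n".join(lines) + "\n"


def all_fixtures() -> dict[str, CrystalDescription]:
    """Stable name -> description map for CLI emission and tests."""
    return {
        "benzene": make_benzene(),
        "ferrocene": make_ferrocene(),
        "azide_symmetric": make_azide(1.24, 1.24),
        "azide_asymmetric": make_azide(1.35, 1.13),
        "water": make_water(),
        "two_waters": make_two_waters(),
        "nacl_contact": make_nacl_contact(),
        "rock_salt": make_rock_salt(),
        "carbonyl": make_carbonyl(),
        "polymer": make_defect("polymer"),
        "clash": make_defect("clash"),
        "overvalence": make_defect("overvalence"),
        "disorder": make_defect("disorder"),
        "compositional": make_defect("compositional"),
    }
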
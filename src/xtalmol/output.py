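"""Writers: MDL Molfile V2000/V3000, SDF, TSV/DWAR tables and SMILES.

Conventions: zero-order coordination bonds serialize as bond type 8 in
V2000 ("any" bond) and type 9 in V3000 ("coordination"); V2000 is limited
to 999 atoms and 999 bonds; charges use the ``M  CHG`` property block.
All writers are pure text producers — identical inputs yield byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .chem_tables import by_symbol
from .perception import Atom, Bond, ChemicalStructure

__all__ = [
    "SdfRecord",
    "MolfileCapacityError",
    "write_molfile_v2000",
    "write_molfile_v3000",
    "write_sdf",
    "write_tsv",
    "strip_coordination_bonds",
    "to_smiles",
]

V2000_MAX_ATOMS = 999
V2000_MAX_BONDS = 999


class MolfileCapacityError(ValueError):
    """V2000 cannot describe more than 999 atoms or 999 bonds."""


@dataclass
class SdfRecord:
    molfile: str
    data: dict[str, str] = field(default_factory=dict)


def _v2000_bond_type(order: int) -> int:
    return 8 if order == 0 else order


def _v3000_bond_type(order: int) -> int:
    return 9 if order == 0 else order


def write_molfile_v2000(structure: ChemicalStructure,
                        title: str = "") -> str:
    n_atoms = len(structure.atoms)
    n_bonds = len(structure.bonds)
    if n_atoms > V2000_MAX_ATOMS or n_bonds > V2000_MAX_BONDS:
        raise MolfileCapacityError(
            f"V2000 molfiles are limited to {V2000_MAX_ATOMS} atoms and "
            f"{V2000_MAX_BONDS} bonds (got {n_atoms} atoms, {n_bonds} bonds)")
    lines = [title, "  xtalmol", ""]
    lines.append(f"{n_atoms:3d}{n_bonds:3d}  0  0  0  0  0  0  0  0999 V2000")
    for atom in structure.atoms:
        x, y, z = atom.cart
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {atom.element:<3s}"
                     f" 0  0  0  0  0  0  0  0  0  0  0  0")
    for bond in structure.bonds:
        lines.append(f"{bond.i + 1:3d}{bond.j + 1:3d}"
                     f"{_v2000_bond_type(bond.order):3d}  0")
    charged = [(i + 1, a.formal_charge)
               for i, a in enumerate(structure.atoms) if a.formal_charge]
    for k in range(0, len(charged), 8):
        chunk = charged[k:k + 8]
        line = f"M  CHG{len(chunk):3d}"
        for idx, q in chunk:
            line += f"{idx:4d}{q:4d}"
        lines.append(line)
    radicals = [(i + 1, 2) for i, a in enumerate(structure.atoms) if a.radical]
    for k in range(0, len(radicals), 8):
        chunk = radicals[k:k + 8]
        line = f"M  RAD{len(chunk):3d}"
        for idx, code in chunk:
            line += f"{idx:4d}{code:4d}"
        lines.append(line)
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def write_molfile_v3000(structure: ChemicalStructure,
                        title: str = "") -> str:
    n_atoms = len(structure.atoms)
    n_bonds = len(structure.bonds)
    lines = [title, "  xtalmol", ""]
    lines.append("  0  0  0  0  0  0  0  0  0  0999 V3000")
    lines.append("M  V30 BEGIN CTAB")
    lines.append(f"M  V30 COUNTS {n_atoms} {n_bonds} 0 0 0")
    lines.append("M  V30 BEGIN ATOM")
    for i, atom in enumerate(structure.atoms, start=1):
        x, y, z = atom.cart
        extra = f" CHG={atom.formal_charge}" if atom.formal_charge else ""
        if atom.radical:
            extra += " RAD=2"
        lines.append(f"M  V30 {i} {atom.element} {x:.4f} {y:.4f} {z:.4f} 0"
                     f"{extra}")
    lines.append("M  V30 END ATOM")
    lines.append("M  V30 BEGIN BOND")
    for k, bond in enumerate(structure.bonds, start=1):
        lines.append(f"M  V30 {k} {_v3000_bond_type(bond.order)} "
                     f"{bond.i + 1} {bond.j + 1}")
    lines.append("M  V30 END BOND")
    lines.append("M  V30 END CTAB")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def write_sdf(records: list[SdfRecord]) -> str:
    """Concatenate records: molfile + data items + ``$$$$`` terminator.

    The validity status and issue list items are always present (failing
    entries are written with their failing status, never omitted).
    """
    chunks = []
    for record in records:
        data = dict(record.data)
        data.setdefault("COD_SDF_ISSUES", "")
        data.setdefault("COD_SDF_VALIDITY_STATUS", "valid")
        body = record.molfile
        if not body.endswith("\n"):
            body += "\n"
        for tag in data:
            body += f"> <{tag}>\n{data[tag]}\n\n"
        body += "$$$$\n"
        chunks.append(body)
    return "".join(chunks)


# --------------------------------------------------------------------------
# TSV / DWAR
# --------------------------------------------------------------------------

TSV_COLUMNS = ("COD ID", "SMILES", "C1-Problems", "Is valid entry")

_DWAR_HEADER = (
    "<datawarrior-fileinfo>\n"
    "<version=\"3.1\">\n"
    "<rowcount=\"{rows}\">\n"
    "</datawarrior-fileinfo>\n"
    "<column properties>\n"
    "<columnName=\"SMILES\">\n"
    "<columnProperty=\"specialType\tSMILES\">\n"
    "</column properties>\n"
)


def write_tsv(rows: list[dict], mode: str = "plain") -> str:
    """Tabular output; ``mode`` is ``plain``, ``header`` or ``dwar``.

    The TSV body is identical across modes; ``header`` prepends the
    column-name row and ``dwar`` additionally prepends a DataWarrior-style
    file header (a documented minimal dialect).
    """
    if mode not in ("plain", "header", "dwar"):
        raise ValueError(f"unknown TSV mode: {mode!r}")
    body_lines = []
    for row in rows:
        body_lines.append("\t".join(str(row.get(col, "")) for col in TSV_COLUMNS))
    body = "".join(line + "\n" for line in body_lines)
    header = "\t".join(TSV_COLUMNS) + "\n"
    if mode == "plain":
        return header + body
    if mode == "header":
        return header + body
    return _DWAR_HEADER.format(rows=len(rows)) + header + body


# --------------------------------------------------------------------------
# Coordination-bond handling
# --------------------------------------------------------------------------

def strip_coordination_bonds(structure: ChemicalStructure,
                             mode: str = "remove") -> ChemicalStructure:
    """Drop all order-0 bonds (``remove``) or set them to order 1
    (``to_single``); everything else is untouched."""
    if mode not in ("remove", "to_single"):
        raise ValueError(f"unknown mode: {mode!r}")
    new_bonds = []
    for bond in structure.bonds:
        if bond.order == 0:
            if mode == "remove":
                continue
            bond = Bond(i=bond.i, j=bond.j, order=1,
                        delocalized=bond.delocalized, length=bond.length,
                        order_fixed=bond.order_fixed)
        new_bonds.append(bond)
    return ChemicalStructure(
        atoms=[Atom(**vars(a)) for a in structure.atoms],
        bonds=new_bonds,
        space_group_number=structure.space_group_number,
        entry_id=structure.entry_id,
        issues=list(structure.issues))


# --------------------------------------------------------------------------
# SMILES
# --------------------------------------------------------------------------

_ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
_DEFAULT_VALENCE = {"B": 3, "C": 4, "N": 3, "O": 2, "P": 3, "S": 2,
                    "F": 1, "Cl": 1, "Br": 1, "I": 1}
_BOND_SYMBOL = {1: "", 2: "=", 3: "#"}


def _canonical_ranks(g: nx.Graph, atoms: list[Atom]) -> dict[int, int]:
    """Deterministic invariant-based ranking (iterative refinement)."""
    inv = {n: (atoms[n].element, g.degree(n), atoms[n].formal_charge,
               atoms[n].attached_hydrogens) for n in g}
    ranks = _ranks_from(inv)
    for _ in range(len(g)):
        new_inv = {n: (ranks[n], tuple(sorted(ranks[m] for m in g[n])))
                   for n in g}
        new_ranks = _ranks_from(new_inv)
        if new_ranks == ranks:
            break
        ranks = new_ranks
    return ranks


def _ranks_from(inv: dict) -> dict[int, int]:
    ordered = sorted(set(inv.values()))
    lookup = {v: i for i, v in enumerate(ordered)}
    return {n: lookup[v] for n, v in inv.items()}


def _implicit_h(structure: ChemicalStructure, idx: int,
                folded_h: int) -> int:
    return structure.atoms[idx].attached_hydrogens + folded_h


def _atom_token(atom: Atom, hcount: int, order_sum: int) -> str:
    sym = atom.element
    if (sym in _ORGANIC_SUBSET and atom.formal_charge == 0
            and not atom.radical
            and order_sum + hcount == _DEFAULT_VALENCE[sym]):
        return sym
    token = sym
    if hcount == 1:
        token += "H"
    elif hcount > 1:
        token += f"H{hcount}"
    q = atom.formal_charge
    if q == 1:
        token += "+"
    elif q == -1:
        token += "-"
    elif q > 1:
        token += f"+{q}"
    elif q < -1:
        token += f"-{abs(q)}"
    return f"[{token}]"


def _component_smiles(structure: ChemicalStructure, nodes: list[int],
                      g: nx.Graph, ranks: dict[int, int]) -> str:
    """SMILES of one connected component (explicit H folded into counts)."""
    atoms = structure.atoms
    # fold explicit hydrogens bonded to exactly one heavy atom
    folded: dict[int, int] = {n: 0 for n in nodes}
    skip: set[int] = set()
    for n in nodes:
        if atoms[n].element != "H":
            continue
        nbrs = [m for m in g[n] if atoms[m].element != "H"]
        if len(list(g[n])) == 1 and len(nbrs) == 1 \
                and atoms[n].formal_charge == 0:
            folded[nbrs[0]] += 1
            skip.add(n)
    emit_nodes = [n for n in nodes if n not in skip]
    if not emit_nodes:  # an isolated H2 / lone hydride
        emit_nodes = list(nodes)
        skip = set()
        folded = {n: 0 for n in nodes}

    bond_order = {}
    for u in emit_nodes:
        for v in g[u]:
            if v in skip:
                continue
            b = structure.bond_between(u, v)
            bond_order[frozenset((u, v))] = b.order if b else 1

    start = min(emit_nodes, key=lambda n: (ranks[n], n))
    visited: set[int] = set()
    ring_numbers: dict[frozenset, int] = {}
    counter = [0]
    tree_edges: set[frozenset] = set()

    # assign ring-closure digits via DFS spanning tree
    order_visit: list[int] = []

    def explore(u: int):
        visited.add(u)
        order_visit.append(u)
        for v in sorted((v for v in g[u] if v not in skip),
                        key=lambda v: (ranks[v], v)):
            e = frozenset((u, v))
            if v not in visited:
                tree_edges.add(e)
                explore(v)
            elif e not in tree_edges and e not in ring_numbers:
                counter[0] += 1
                ring_numbers[e] = counter[0]

    explore(start)

    out: list[str] = []

    def emit(u: int, parent: int | None):
        atom = atoms[u]
        hcount = _implicit_h(structure, u, folded[u])
        osum = sum(bond_order[frozenset((u, v))]
                   for v in g[u] if v not in skip)
        out.append(_atom_token(atom, hcount, osum))
        closures = [(num, e) for e, num in ring_numbers.items() if u in e]
        closures.sort()
        for num, e in closures:
            v = next(iter(e - {u}))
            if v in emitted:  # second visit closes the ring
                out.append(_BOND_SYMBOL.get(bond_order[e], "") + _ring_digit(num))
            else:
                out.append(_BOND_SYMBOL.get(bond_order[e], "") + _ring_digit(num))
        emitted.add(u)
        children = [v for v in sorted((v for v in g[u] if v not in skip),
                                      key=lambda v: (ranks[v], v))
                    if frozenset((u, v)) in tree_edges and v != parent
                    and v not in emitted]
        for k, v in enumerate(children):
            sym = _BOND_SYMBOL.get(bond_order[frozenset((u, v))], "")
            if k < len(children) - 1:
                out.append("(" + sym)
                emit(v, u)
                out.append(")")
            else:
                out.append(sym)
                emit(v, u)

    emitted: set[int] = set()
    emit(start, None)
    return "".join(out)


def _ring_digit(num: int) -> str:
    return str(num) if num < 10 else f"%{num}"


def to_smiles(structure: ChemicalStructure,
              scope: str = "components") -> list[str]:
    """SMILES strings for one of three scopes.

    ``crystal``  — one dot-joined string; order-0 bonds become single.
    ``components`` — one string per connected component (order-0 as single).
    ``ligands`` — order-0 bonds removed first, then one string per
    component (each ligand and each bare metal separately).
    """
    if scope not in ("crystal", "components", "ligands"):
        raise ValueError(f"unknown SMILES scope: {scope!r}")
    mode = "remove" if scope == "ligands" else "to_single"
    stripped = strip_coordination_bonds(structure, mode)
    g = nx.Graph()
    g.add_nodes_from(range(len(stripped.atoms)))
    for bond in stripped.bonds:
        g.add_edge(bond.i, bond.j)
    ranks = _canonical_ranks(g, stripped.atoms)
    components = sorted(nx.connected_components(g),
                        key=lambda c: (min((ranks[n], n) for n in c)))
    strings = [_component_smiles(stripped, sorted(comp), g, ranks)
               for comp in components]
    if scope == "crystal":
        return [".".join(strings)] if strings else [""]
    return strings
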
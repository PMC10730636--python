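"""Reader for the crystallographic input dialect plus symmetry/cell algebra.

Supported CIF subset: a single ``data_`` block, scalar items, ``loop_``
tables, single/double-quoted values and semicolon text fields, which covers
the fixed vocabulary the pipeline consumes (cell, symmetry operators, atom
sites, formula, provenance and maintainer markup).  CIF2 and dictionary
validation are out of scope.

Conventions: fractional coordinates are wrapped into ``[0, 1)``; Cartesian
coordinates are in Angstrom with *a* along *x* and *b* in the *xy* plane.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import chem_tables

__all__ = [
    "UnitCell",
    "SymmetryOperator",
    "AtomSite",
    "CrystalDescription",
    "CifParseError",
    "UnknownElementError",
    "MissingCoordinatesError",
    "InsufficientCellError",
    "InsufficientSymmetryError",
    "read_cif",
    "parse_symop",
    "format_symop",
    "apply_symop",
    "frac_to_cartesian",
    "cartesian_matrix",
]


class CifParseError(ValueError):
    """Base class for failures while reading a crystal description."""


class UnknownElementError(CifParseError):
    """An atom site uses a chemical symbol absent from the element table."""


class MissingCoordinatesError(CifParseError):
    """A crystal description lacks usable atomic coordinates."""


class InsufficientCellError(CifParseError):
    """Unit-cell parameters are absent or degenerate."""


class InsufficientSymmetryError(CifParseError):
    """Space-group/symmetry information is absent or malformed."""


# --------------------------------------------------------------------------
# Core types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise InsufficientCellError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise InsufficientCellError(f"cell angle {name} out of (0, 180)")
        if self.volume() <= 0:
            raise InsufficientCellError("degenerate unit cell (volume <= 0)")

    def metric_tensor(self) -> np.ndarray:
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array([
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ])

    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        arg = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)


@dataclass(frozen=True)
class SymmetryOperator:
    rotation: tuple[tuple[Fraction, ...], ...]
    translation: tuple[Fraction, ...]

    def __post_init__(self):
        rot = np.array([[float(x) for x in row] for row in self.rotation])
        det = round(float(np.linalg.det(rot)))
        if det not in (1, -1):
            raise InsufficientSymmetryError(
                f"symmetry rotation determinant must be +-1, got {det}")

    @property
    def is_identity(self) -> bool:
        ident = tuple(tuple(Fraction(int(i == j)) for j in range(3)) for i in range(3))
        return self.rotation == ident and all(t == 0 for t in self.translation)

    def rotation_array(self) -> np.ndarray:
        return np.array([[float(x) for x in row] for row in self.rotation])

    def translation_array(self) -> np.ndarray:
        return np.array([float(t) for t in self.translation])


IDENTITY_OP = SymmetryOperator(
    rotation=tuple(tuple(Fraction(int(i == j)) for j in range(3)) for i in range(3)),
    translation=(Fraction(0), Fraction(0), Fraction(0)),
)


@dataclass
class AtomSite:
    label: str
    element: str
    frac: tuple[float, float, float]
    occupancy: float = 1.0
    attached_hydrogens: int = 0
    disorder_assembly: str | None = None
    disorder_group: str | None = None

    def __post_init__(self):
        chem_tables.by_symbol(self.element)  # raises for unknown symbols
        if not 0.0 < self.occupancy <= 1.0:
            raise CifParseError(
                f"site {self.label}: occupancy must be in (0, 1], "
                f"got {self.occupancy}")
        if self.attached_hydrogens < 0:
            raise CifParseError(
                f"site {self.label}: attached_hydrogens must be >= 0")


@dataclass
class CrystalDescription:
    cell: UnitCell
    operators: list[SymmetryOperator]
    sites: list[AtomSite]
    declared_formula: dict[str, int] = field(default_factory=dict)
    space_group_number: int | None = None
    z_formula_units: int | None = None
    doi: str | None = None
    journal: str | None = None
    year: str | None = None
    entry_id: str | None = None
    markup_flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not any(op.is_identity for op in self.operators):
            raise InsufficientSymmetryError(
                "symmetry operator list lacks the identity")
        if (self.space_group_number is not None
                and not 1 <= self.space_group_number <= 230):
            raise InsufficientSymmetryError(
                f"space group number out of [1, 230]: {self.space_group_number}")


# --------------------------------------------------------------------------
# Symmetry operator parsing / algebra
# --------------------------------------------------------------------------

_TERM_RE = re.compile(
    r"([+-]?)\s*(?:(\d+(?:\.\d+)?)(?:\s*/\s*(\d+))?\s*\*?\s*)?([xyz])?")


def _parse_component(comp: str) -> tuple[list[Fraction], Fraction]:
    """One symop component like ``x+1/2`` -> (row of 3 coeffs, translation)."""
    comp = comp.strip().lower()
    if not comp:
        raise CifParseError("empty symmetry operator component")
    row = [Fraction(0)] * 3
    trans = Fraction(0)
    pos = 0
    matched_any = False
    while pos < len(comp):
        m = _TERM_RE.match(comp, pos)
        if not m or m.end() == pos:
            raise CifParseError(f"malformed symmetry operator component: {comp!r}")
        sign, num, den, var = m.groups()
        coeff = Fraction(1)
        if num is not None:
            coeff = Fraction(num) if den is None else Fraction(int(num), int(den))
        if sign == "-":
            coeff = -coeff
        if var is not None:
            row["xyz".index(var)] += coeff
        elif num is not None:
            trans += coeff
        else:
            raise CifParseError(f"malformed symmetry operator component: {comp!r}")
        matched_any = True
        pos = m.end()
    if not matched_any:
        raise CifParseError(f"malformed symmetry operator component: {comp!r}")
    return row, trans


def parse_symop(s: str) -> SymmetryOperator:
    """Parse an ``x,y,z``-style operator string."""
    parts = s.split(",")
    if len(parts) != 3:
        raise CifParseError(f"symmetry operator must have 3 components: {s!r}")
    rows = []
    trans = []
    for comp in parts:
        row, t = _parse_component(comp)
        rows.append(tuple(row))
        trans.append(t % 1)
    return SymmetryOperator(rotation=tuple(rows), translation=tuple(trans))


def format_symop(op: SymmetryOperator) -> str:
    """Inverse of :func:`parse_symop` (canonical spelling)."""
    comps = []
    for row, t in zip(op.rotation, op.translation):
        terms = []
        for coeff, var in zip(row, "xyz"):
            if coeff == 0:
                continue
            if coeff == 1:
                terms.append(f"+{var}" if terms else var)
            elif coeff == -1:
                terms.append(f"-{var}")
            else:
                sign = "+" if coeff > 0 else "-"
                mag = abs(coeff)
                prefix = sign if terms or sign == "-" else ""
                terms.append(f"{prefix}{mag}*{var}")
        if t != 0:
            sign = "+" if t > 0 else "-"
            prefix = sign if terms or sign == "-" else ""
            terms.append(f"{prefix}{abs(t)}")
        comps.append("".join(terms) if terms else "0")
    return ",".join(comps)


def apply_symop(op: SymmetryOperator, frac, wrap: bool = False) -> np.ndarray:
    """Apply rotation+translation to fractional coordinates."""
    out = op.rotation_array() @ np.asarray(frac, dtype=float) + op.translation_array()
    if wrap:
        out = out % 1.0
    return out


# --------------------------------------------------------------------------
# Cell algebra
# --------------------------------------------------------------------------

def cartesian_matrix(cell: UnitCell) -> np.ndarray:
    """Orthogonalization matrix M with cart = M @ frac (a along x)."""
    a, b, c = cell.a, cell.b, cell.c
    alpha, beta, gamma = (math.radians(x) for x in (cell.alpha, cell.beta, cell.gamma))
    cos_a, cos_b, cos_g = math.cos(alpha), math.cos(beta), math.cos(gamma)
    sin_g = math.sin(gamma)
    if abs(sin_g) < 1e-12:
        raise ValueError("degenerate cell: gamma ~ 0 or 180 degrees")
    cx = c * cos_b
    cy = c * (cos_a - cos_b * cos_g) / sin_g
    cz_sq = c * c - cx * cx - cy * cy
    if cz_sq <= 0:
        raise ValueError("degenerate cell: inconsistent angles")
    return np.array([
        [a, b * cos_g, cx],
        [0.0, b * sin_g, cy],
        [0.0, 0.0, math.sqrt(cz_sq)],
    ])


def frac_to_cartesian(cell: UnitCell, frac) -> np.ndarray:
    return cartesian_matrix(cell) @ np.asarray(frac, dtype=float)


# --------------------------------------------------------------------------
# CIF reading
# --------------------------------------------------------------------------

def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            # semicolon text field
            value_lines = [line[1:]]
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                value_lines.append(lines[i])
                i += 1
            tokens.append("\n".join(value_lines))
            i += 1
            continue
        pos = 0
        n = len(line)
        while pos < n:
            ch = line[pos]
            if ch in " \t":
                pos += 1
                continue
            if ch == "#":
                break
            if ch in "'\"":
                end = line.find(ch, pos + 1)
                while end != -1 and end + 1 < n and line[end + 1] not in " \t":
                    end = line.find(ch, end + 1)
                if end == -1:
                    raise CifParseError(f"unterminated quoted string: {line!r}")
                tokens.append(line[pos + 1:end])
                pos = end + 1
            else:
                m = re.match(r"\S+", line[pos:])
                tokens.append(m.group(0))
                pos += m.end()
        i += 1
    return tokens


def _parse_items(text: str) -> dict[str, object]:
    """CIF block -> {tag: value} with loops as {tag: [values...]}."""
    tokens = _tokenize(text)
    items: dict[str, object] = {}
    i = 0
    n = len(tokens)
    seen_data = False
    while i < n:
        tok = tokens[i]
        low = tok.lower()
        if low.startswith("data_"):
            if seen_data:
                raise CifParseError("multiple data blocks are not supported")
            seen_data = True
            items.setdefault("_data_block_name", tok[5:])
            i += 1
        elif low == "loop_":
            i += 1
            tags = []
            while i < n and tokens[i].startswith("_"):
                tags.append(tokens[i].lower())
                i += 1
            values: list[str] = []
            while i < n:
                tok2 = tokens[i]
                tl = tok2.lower()
                if tok2.startswith("_") or tl == "loop_" or tl.startswith("data_"):
                    break
                values.append(tok2)
                i += 1
            if not tags:
                raise CifParseError("loop_ without tags")
            if len(values) % len(tags) != 0:
                raise CifParseError("loop_ row length mismatch")
            cols: dict[str, list[str]] = {t: [] for t in tags}
            for j, v in enumerate(values):
                cols[tags[j % len(tags)]].append(v)
            items.update(cols)
        elif tok.startswith("_"):
            if i + 1 >= n:
                raise CifParseError(f"item {tok} has no value")
            items[low] = tokens[i + 1]
            i += 2
        else:
            # stray value outside any item; ignore (lenient)
            i += 1
    return items


_NUM_RE = re.compile(r"^[+-]?\d*\.?\d+(?:[eE][+-]?\d+)?")


def _numeric(value: str, context: str) -> float:
    # strip the standard-uncertainty suffix "1.234(5)"
    m = _NUM_RE.match(value)
    if not m:
        raise CifParseError(f"non-numeric value for {context}: {value!r}")
    return float(m.group(0))


def _clean_symbol(raw: str) -> str:
    m = re.match(r"([A-Za-z]{1,2})", raw)
    if not m:
        raise UnknownElementError(f"unrecognized chemical symbol: {raw!r}")
    sym = m.group(1)
    sym = sym[0].upper() + sym[1:].lower()
    if sym not in chem_tables.element_table():
        # one-letter fallback for labels like "CA1" meaning carbon
        if sym[0] in chem_tables.element_table():
            sym = sym[0]
        else:
            raise UnknownElementError(f"unrecognized chemical symbol: {raw!r}")
    return sym


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string like ``'C6 H12 O6'``."""
    counts: dict[str, int] = {}
    for part in formula.replace(",", " ").split():
        m = re.match(r"^([A-Z][a-z]?)(\d*\.?\d*)$", part)
        if not m:
            continue
        sym, num = m.groups()
        if sym not in chem_tables.element_table():
            continue
        counts[sym] = counts.get(sym, 0) + int(round(float(num))) if num else \
            counts.get(sym, 0) + 1
    return counts


_MARKUP_ITEMS = {
    "_cod_duplicate_entry": "duplicate",
    "_cod_suboptimal_structure": "suboptimal",
    "_cod_theoretical_structure": "theoretical",
    "_cod_manual_exclusion": "manual-exclusion",
}

_SYMOP_TAGS = ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz")


def read_cif(text: str) -> CrystalDescription:
    """Parse a single-data-block CIF document into a crystal description."""
    items = _parse_items(text)

    def get(tag: str):
        return items.get(tag)

    for tag in ("_cell_length_a", "_cell_length_b", "_cell_length_c"):
        if tag not in items:
            raise InsufficientCellError(f"missing required cell item {tag}")
    cell = UnitCell(
        a=_numeric(str(get("_cell_length_a")), "_cell_length_a"),
        b=_numeric(str(get("_cell_length_b")), "_cell_length_b"),
        c=_numeric(str(get("_cell_length_c")), "_cell_length_c"),
        alpha=_numeric(str(get("_cell_angle_alpha") or "90"), "_cell_angle_alpha"),
        beta=_numeric(str(get("_cell_angle_beta") or "90"), "_cell_angle_beta"),
        gamma=_numeric(str(get("_cell_angle_gamma") or "90"), "_cell_angle_gamma"),
    )

    operators: list[SymmetryOperator] = []
    for tag in _SYMOP_TAGS:
        raw = get(tag)
        if raw is None:
            continue
        raw_list = raw if isinstance(raw, list) else [raw]
        operators = [parse_symop(s) for s in raw_list]
        break
    if not operators:
        operators = [IDENTITY_OP]
    if not any(op.is_identity for op in operators):
        raise InsufficientSymmetryError(
            "symmetry operator list lacks the identity operation")

    labels = get("_atom_site_label")
    if labels is None:
        raise MissingCoordinatesError("no atom sites present")
    if not isinstance(labels, list):
        labels = [labels]

    def column(tag: str, default=None):
        raw = get(tag)
        if raw is None:
            return [default] * len(labels)
        out = raw if isinstance(raw, list) else [raw]
        if len(out) != len(labels):
            raise CifParseError(f"column {tag} length mismatch")
        return out

    for tag in ("_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z"):
        if tag not in items:
            raise MissingCoordinatesError(f"missing atomic coordinates ({tag})")

    xs = column("_atom_site_fract_x")
    ys = column("_atom_site_fract_y")
    zs = column("_atom_site_fract_z")
    symbols = column("_atom_site_type_symbol")
    occs = column("_atom_site_occupancy")
    attached = column("_atom_site_attached_hydrogens")
    assemblies = column("_atom_site_disorder_assembly")
    groups = column("_atom_site_disorder_group")

    sites: list[AtomSite] = []
    for k, label in enumerate(labels):
        raw_sym = symbols[k] if symbols[k] not in (None, ".", "?") else label
        element = _clean_symbol(str(raw_sym))
        for coord, tag in ((xs[k], "x"), (ys[k], "y"), (zs[k], "z")):
            if coord in (None, ".", "?"):
                raise MissingCoordinatesError(
                    f"site {label}: missing fractional coordinate {tag}")
        frac = tuple(_numeric(str(v), f"coordinate of {label}") % 1.0
                     for v in (xs[k], ys[k], zs[k]))
        occ_raw = occs[k]
        occ = 1.0 if occ_raw in (None, ".", "?") else _numeric(str(occ_raw), "occupancy")
        att_raw = attached[k]
        att = 0 if att_raw in (None, ".", "?") else int(_numeric(str(att_raw), "H"))
        asm = None if assemblies[k] in (None, ".", "?") else str(assemblies[k])
        grp = None if groups[k] in (None, ".", "?") else str(groups[k])
        sites.append(AtomSite(label=str(label), element=element, frac=frac,
                              occupancy=occ, attached_hydrogens=att,
                              disorder_assembly=asm, disorder_group=grp))

    sg_raw = get("_space_group_it_number") or get("_symmetry_int_tables_number")
    sg = int(_numeric(str(sg_raw), "space group number")) if sg_raw else None

    z_raw = get("_cell_formula_units_z")
    z_units = int(_numeric(str(z_raw), "Z")) if z_raw not in (None, ".", "?") else None

    formula_raw = get("_chemical_formula_sum")
    declared = parse_formula(str(formula_raw)) if formula_raw not in (None, ".", "?") else {}

    doi = get("_journal_paper_doi")
    doi = None if doi in (None, ".", "?") else str(doi)
    journal = get("_journal_name_full")
    journal = None if journal in (None, ".", "?") else str(journal)
    year = get("_journal_year")
    year = None if year in (None, ".", "?") else str(year)
    entry_id = get("_cod_database_code")
    entry_id = str(entry_id) if entry_id not in (None, ".", "?") else \
        str(get("_data_block_name") or "") or None

    markup: set[str] = set()
    for tag, flag in _MARKUP_ITEMS.items():
        val = get(tag)
        if val not in (None, ".", "?", "no", "n"):
            markup.add(flag)

    return CrystalDescription(
        cell=cell, operators=operators, sites=sites,
        declared_formula=declared, space_group_number=sg,
        z_formula_units=z_units, doi=doi, journal=journal, year=year,
        entry_id=entry_id, markup_flags=markup,
    )
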
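"""Element property tables and the bond-length distribution class table.

The perception and validation steps are driven by two data sets bundled
with the package:

* ``elements.yaml`` — per-element properties (covalent radii, allowed
  valences/charges, metal and pi-capability classification).
* ``bond_classes.tsv`` — Gaussian models (mean, sigma, count) of bond-length
  distributions keyed by element pair, bond order and an optional
  pi-electron context of the two bonded atoms.

The pi context of a bond class is the pair ``(pi_a, pi_b)`` of pi-electron
counts of the bonded atoms; a ``*`` entry acts as a wildcard matching any
context.  This two-number descriptor is a documented approximation of the
richer neighbour-environment keys used by reference distribution sets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import yaml

__all__ = [
    "ElementProperties",
    "BondClass",
    "BondClassTable",
    "InvalidElementError",
    "BondTableFormatError",
    "element_table",
    "by_symbol",
    "by_number",
    "is_metal",
    "load_bond_classes",
    "default_bond_classes",
    "length_zscore",
]

#: Atomic-number ranges classified as metals (inherited convention covering
#: alkali, alkaline-earth, transition, lanthanide, actinide and
#: post-transition metals plus Sb and Po).
METAL_RANGES: tuple[tuple[int, int], ...] = (
    (3, 4), (11, 13), (19, 31), (37, 51), (55, 84), (87, 103),
)

#: Elements participating in pi-electron bookkeeping.
PI_CAPABLE_SYMBOLS = frozenset(
    {"B", "C", "N", "O", "Si", "P", "S", "Cl", "Ge", "As", "Se", "Br",
     "Te", "I"}
)


class InvalidElementError(ValueError):
    """Raised for atomic numbers / symbols outside the known table."""


class BondTableFormatError(ValueError):
    """Raised when a bond-class table violates the expected TSV schema."""


@dataclass(frozen=True)
class ElementProperties:
    symbol: str
    Z: int
    covalent_radius: float
    max_valences: tuple[int, ...]
    allowed_charges: frozenset[int]
    oxidation_states: frozenset[int]
    is_metal: bool
    pi_capable: bool

    @property
    def max_valence(self) -> int:
        return max(self.max_valences)


def is_metal(z: int) -> bool:
    """Whether atomic number *z* belongs to the metal range union."""
    if not isinstance(z, int) or not 1 <= z <= 118:
        raise InvalidElementError(f"atomic number out of range: {z!r}")
    return any(lo <= z <= hi for lo, hi in METAL_RANGES)


def _load_element_yaml() -> list[dict]:
    text = (importlib.resources.files("xtalmol.data") / "elements.yaml").read_text()
    return yaml.safe_load(text)["elements"]


@lru_cache(maxsize=1)
def element_table() -> dict[str, ElementProperties]:
    """Mapping of element symbol to :class:`ElementProperties`."""
    table: dict[str, ElementProperties] = {}
    for row in _load_element_yaml():
        props = ElementProperties(
            symbol=row["symbol"],
            Z=int(row["Z"]),
            covalent_radius=float(row["covalent_radius"]),
            max_valences=tuple(row["max_valences"]),
            allowed_charges=frozenset(row["allowed_charges"]),
            oxidation_states=frozenset(row["oxidation_states"]),
            is_metal=bool(row["is_metal"]),
            pi_capable=bool(row["pi_capable"]),
        )
        table[props.symbol] = props
    return table


@lru_cache(maxsize=1)
def _by_number() -> dict[int, ElementProperties]:
    return {p.Z: p for p in element_table().values()}


def by_symbol(symbol: str) -> ElementProperties:
    try:
        return element_table()[symbol]
    except KeyError:
        raise InvalidElementError(f"unrecognized chemical symbol: {symbol!r}") from None


def by_number(z: int) -> ElementProperties:
    try:
        return _by_number()[z]
    except KeyError:
        raise InvalidElementError(f"no element with atomic number {z!r}") from None


# --------------------------------------------------------------------------
# Bond classes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BondClass:
    """Gaussian bond-length model for one (element pair, order, context)."""

    element_pair: tuple[int, int]  # ordered (min Z, max Z)
    order: int
    context: tuple[int | None, int | None]  # pi counts; None is a wildcard
    mean: float
    sigma: float
    count: int

    def zscore(self, d: float) -> float:
        return (d - self.mean) / self.sigma

    @property
    def key(self) -> tuple:
        return (self.element_pair, self.order, self.context)


def length_zscore(cls: BondClass, d: float) -> float:
    """Signed deviation of a bond length from its class mean in sigmas."""
    if d <= 0:
        raise ValueError(f"bond length must be positive, got {d}")
    return cls.zscore(d)


_REQUIRED_COLUMNS = {"elem_a", "elem_b", "order", "pi_a", "pi_b",
                     "mean", "sigma", "count"}


def _parse_ctx(token: str) -> int | None:
    return None if token == "*" else int(token)


class BondClassTable:
    """Lookup structure over a set of :class:`BondClass` entries."""

    def __init__(self, classes: list[BondClass]):
        self.classes = list(classes)
        self._by_key: dict[tuple, BondClass] = {}
        self._by_pair_order: dict[tuple, list[BondClass]] = {}
        for cls in self.classes:
            if cls.key in self._by_key:
                raise BondTableFormatError(f"duplicate bond class key: {cls.key}")
            self._by_key[cls.key] = cls
            self._by_pair_order.setdefault((cls.element_pair, cls.order), []).append(cls)

    def __len__(self) -> int:
        return len(self.classes)

    def lookup(self, za: int, zb: int, order: int,
               context: tuple[int, int] | None = None) -> BondClass | None:
        """Best class for an element pair and order.

        When *context* is given (pi counts of the two atoms, in the same
        orientation as ``za, zb``), a class whose context matches exactly is
        preferred over a wildcard class; with no context the wildcard (or
        the sole available) class is returned.
        """
        pair = (min(za, zb), max(za, zb))
        if context is not None and za > zb:
            context = (context[1], context[0])
        candidates = self._by_pair_order.get((pair, order))
        if not candidates:
            return None
        if context is not None:
            for cls in candidates:
                if cls.context == context:
                    return cls
            for cls in candidates:
                ca, cb = cls.context
                if ((ca is None or ca == context[0])
                        and (cb is None or cb == context[1])):
                    return cls
        for cls in candidates:
            if cls.context == (None, None):
                return cls
        return min(candidates,
                   key=lambda c: tuple(-1 if x is None else x for x in c.context))

    def rank_orders(self, za: int, zb: int, d: float,
                    contexts: tuple[int, int] | None = None,
                    orders=(1, 2, 3)) -> list[tuple[int, float]]:
        """Candidate bond orders sorted by |z| against their best class.

        Returns ``[(order, |z|), ...]`` ascending by absolute z-score with
        ties broken toward the lower order, or an empty list when no class
        matches the element pair at all (caller falls back to a single
        bond).
        """
        if d <= 0:
            raise ValueError(f"bond length must be positive, got {d}")
        ranked = []
        for order in orders:
            cls = self.lookup(za, zb, order, contexts)
            if cls is not None:
                ranked.append((order, abs(cls.zscore(d))))
        ranked.sort(key=lambda t: (t[1], t[0]))
        return ranked


def load_bond_classes(text: str) -> BondClassTable:
    """Parse a bond-class TSV document (header row + one class per line)."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise BondTableFormatError("empty bond class table")
    header = lines[0].rstrip("\n").split("\t")
    missing = _REQUIRED_COLUMNS - set(header)
    if missing:
        raise BondTableFormatError(f"missing columns: {sorted(missing)}")
    idx = {name: header.index(name) for name in header}
    classes: list[BondClass] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise BondTableFormatError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}")
        try:
            za = by_symbol(fields[idx["elem_a"]]).Z
            zb = by_symbol(fields[idx["elem_b"]]).Z
            order = int(fields[idx["order"]])
            ctx = (_parse_ctx(fields[idx["pi_a"]]), _parse_ctx(fields[idx["pi_b"]]))
            mean = float(fields[idx["mean"]])
            sigma = float(fields[idx["sigma"]])
            count = int(fields[idx["count"]])
        except InvalidElementError:
            raise
        except ValueError as exc:
            raise BondTableFormatError(f"line {lineno}: {exc}") from exc
        if sigma <= 0:
            raise ValueError(f"line {lineno}: sigma must be > 0, got {sigma}")
        if mean <= 0:
            raise ValueError(f"line {lineno}: mean must be > 0, got {mean}")
        if order not in (1, 2, 3):
            raise ValueError(f"line {lineno}: order must be 1, 2 or 3, got {order}")
        if za > zb:
            za, zb = zb, za
            ctx = (ctx[1], ctx[0])
        classes.append(BondClass((za, zb), order, ctx, mean, sigma, count))
    return BondClassTable(classes)


@lru_cache(maxsize=1)
def default_bond_classes() -> BondClassTable:
    """The bond-class table bundled with the package."""
    text = (importlib.resources.files("xtalmol.data") / "bond_classes.tsv").read_text()
    return load_bond_classes(text)
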
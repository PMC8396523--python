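"""Elemental-composition arithmetic and mass computation.

All mass bookkeeping in this package is done on multisets of element counts
(:class:`ElementalComposition`).  Monoisotopic and average masses are computed
from a fixed atomic-mass snapshot shipped as package data
(``data/elements.tsv``), so results are bit-stable across environments.

The objects defined here are the basis of every mass shift the tool reports:
a lysine residue (+128.09 Da), a hexose residue (+162.05 Da, shared by
galactosylation and glycation, which are isobaric at the intact level), a
sialic-acid residue (+291.10 Da), and the loss of the light-chain N-terminal
pentapeptide QIVLS (-540.33 Da).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ElementalComposition",
    "MassValue",
    "ModDelta",
    "WATER",
    "PROTON_MASS",
    "parse_formula",
    "mass",
    "sequence_composition",
    "apply_mods",
    "element_masses",
    "residue_table",
    "load_mod_registry",
]

#: Mass of a proton (charge carrier in positive-mode ESI), Da.
PROTON_MASS = 1.007276466879

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable formulas or unknown element/residue symbols."""


@dataclass(frozen=True)
class MassValue:
    """Monoisotopic and average mass of a composition, in Da."""

    mono: float
    avg: float

    def __add__(self, other: "MassValue") -> "MassValue":
        return MassValue(self.mono + other.mono, self.avg + other.avg)


class ElementalComposition(dict):
    """Multiset of element counts; counts may be negative, zeros are dropped.

    Behaves as a ``dict`` of element symbol -> signed integer count, closed
    under addition/subtraction and integer scaling.
    """

    def __init__(self, counts: Mapping[str, int] | None = None):
        super().__init__()
        if counts:
            for el, n in counts.items():
                if n:
                    self[el] = int(n)

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalComposition(out)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({el: n * k for el, n in self.items()})

    __rmul__ = __mul__

    def __neg__(self) -> "ElementalComposition":
        return self * -1

    def to_string(self) -> str:
        """Canonical Hill-order formula (C, H first, then alphabetical).

        Negative counts are rendered with an explicit sign so the string
        round-trips through :func:`parse_formula` only for non-negative
        compositions; signed compositions are for display.
        """
        order = sorted(self, key=lambda el: (el != "C", el != "H", el))
        parts = []
        for el in order:
            n = self[el]
            parts.append(f"{el}{n}" if n != 1 else el)
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalComposition({dict(self)!r})"


@dataclass(frozen=True)
class ModDelta:
    """A named composition change (may be negative), e.g. one hexose residue."""

    name: str
    delta: ElementalComposition = field(default_factory=ElementalComposition)

    def inverse(self) -> "ModDelta":
        return ModDelta(f"-{self.name}", -self.delta)


def parse_formula(formula: str) -> ElementalComposition:
    """Parse an element-count string like ``"C6H10O5"``.

    Empty string parses to the empty composition.  Unknown element symbols
    (not in the bundled mass table) raise :class:`FormulaError`.
    """
    comp: dict[str, int] = {}
    pos = 0
    table = element_masses()
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula at {formula[pos:]!r}")
        pos = m.end()
        el, digits = m.groups()
        if el not in table:
            raise FormulaError(f"unknown element symbol {el!r} in {formula!r}")
        comp[el] = comp.get(el, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise FormulaError(f"unparseable formula at {formula[pos:]!r}")
    return ElementalComposition(comp)


_ELEMENTS: dict[str, tuple[float, float]] | None = None
_RESIDUES: dict[str, ElementalComposition] | None = None


def _read_data(name: str) -> str:
    return resources.files("mabquant.data").joinpath(name).read_text()


def element_masses() -> dict[str, tuple[float, float]]:
    """Bundled atomic-mass snapshot: element -> (mono, avg) in Da."""
    global _ELEMENTS
    if _ELEMENTS is None:
        table = {}
        for line in _read_data("elements.tsv").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            el, mono, avg = line.split("\t")
            table[el] = (float(mono), float(avg))
        _ELEMENTS = table
    return _ELEMENTS


def residue_table() -> dict[str, ElementalComposition]:
    """Amino-acid residue compositions (residue = amino acid - water)."""
    global _RESIDUES
    if _RESIDUES is None:
        table = {}
        for line in _read_data("residues.tsv").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code, formula = line.split("\t")
            table[code] = parse_formula(formula)
        _RESIDUES = table
    return _RESIDUES


def load_mod_registry(path: str | None = None) -> dict[str, ModDelta]:
    """Load the modification registry (name -> :class:`ModDelta`).

    Without ``path`` the bundled registry is used.  Entries are either a
    formula string (all counts positive) or an element -> signed-count map.
    """
    if path is None:
        raw = yaml.safe_load(_read_data("mods.yaml"))
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    registry = {}
    for name, value in raw.items():
        if isinstance(value, str):
            delta = parse_formula(value)
        else:
            delta = ElementalComposition({el: int(n) for el, n in value.items()})
        registry[name] = ModDelta(name, delta)
    return registry


def mass(comp: Mapping[str, int]) -> MassValue:
    """Monoisotopic and average mass of a composition, in Da.

    Linear in the composition: ``mass(a + b) == mass(a) + mass(b)``.
    """
    table = element_masses()
    mono = avg = 0.0
    for el, n in comp.items():
        try:
            m_mono, m_avg = table[el]
        except KeyError:
            raise FormulaError(f"unknown element symbol {el!r}") from None
        mono += n * m_mono
        avg += n * m_avg
    return MassValue(mono, avg)


def sequence_composition(seq: str, water: bool = True) -> ElementalComposition:
    """Composition of an amino-acid sequence.

    With ``water=True`` the free-peptide composition (sum of residues plus one
    water) is returned; with ``water=False`` the bare residue sum, the right
    quantity for internal gains/losses such as the QIVLS truncation
    (-540.33 Da).
    """
    residues = residue_table()
    comp = ElementalComposition()
    for code in seq:
        try:
            comp = comp + residues[code]
        except KeyError:
            raise FormulaError(f"unknown residue code {code!r}") from None
    if water and seq:
        comp = comp + parse_formula("H2O")
    return comp


def apply_mods(
    base: Mapping[str, int], mods: Iterable[ModDelta]
) -> ElementalComposition:
    """Apply modification deltas to a base composition (order-independent)."""
    comp = ElementalComposition(base)
    for mod in mods:
        comp = comp + mod.delta
    return comp


WATER = parse_formula("H2O")
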
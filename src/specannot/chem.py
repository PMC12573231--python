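"""Elemental formulas and monoisotopic mass arithmetic.

Every mass in the package flows through :class:`ElementalFormula`, a signed
multiset of ``(isotope, element)`` counts.  Signed counts make neutral losses
and linker chemistry first-class: the disulfide bridge is simply the formula
``H-2``, and the phospho neutral loss is ``H3O4P1``.

Monoisotopic atomic masses are embedded (IUPAC/AME values, >= 9 decimals) so
that mass computation is reproducible without any external resource.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

__all__ = [
    "ElementalFormula",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "mz",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "WATER",
    "AMMONIA",
    "CARBON_MONOXIDE",
    "HYDROGEN",
    "AMINO_ACIDS",
    "AMBIGUOUS_ALTERNATIVES",
    "MONOSACCHARIDES",
    "DEFAULT_OXONIUM_LOSSES",
]


class FormulaError(ValueError):
    """Raised for malformed formula text or unknown elements/isotopes."""


#: Mass of the most abundant isotope, per element symbol (Da).
MONOISOTOPIC_MASSES: Dict[str, float] = {
    "H": 1.007825031898,
    "C": 12.0,
    "N": 14.003074004251,
    "O": 15.994914619257,
    "P": 30.973761998015,
    "S": 31.972071174229,
    "Se": 79.916521800,
    "F": 18.998403162067,
    "Na": 22.989769282019,
    "K": 38.963706486449,
    "Cl": 34.968852682108,
    "Br": 78.918337600,
    "I": 126.904471900,
    "Si": 27.976926534649,
    "Ca": 39.962590850,
    "Mg": 23.985041689452,
    "Fe": 55.934935900,
    "Zn": 63.929141800,
    "Cu": 62.929597200,
    "Mn": 54.938043000,
    "B": 11.009305167,
    "Li": 7.016003434,
    "Al": 26.981538408,
    "Ni": 57.935342000,
    "Co": 58.933193500,
    "As": 74.921594500,
    "Mo": 97.905404800,
    "Ag": 106.905091600,
    "Pt": 194.964791700,
    "Au": 196.966570100,
    "Hg": 201.970643000,
}

#: Masses for explicitly isotope-labelled entries, keyed ``(mass number, symbol)``.
ISOTOPE_MASSES: Dict[Tuple[int, str], float] = {
    (1, "H"): 1.007825031898,
    (2, "H"): 2.014101777844,
    (3, "H"): 3.016049281320,
    (12, "C"): 12.0,
    (13, "C"): 13.003354835053,
    (14, "N"): 14.003074004251,
    (15, "N"): 15.000108898266,
    (16, "O"): 15.994914619257,
    (17, "O"): 16.999131757000,
    (18, "O"): 17.999159612136,
    (32, "S"): 31.972071174229,
    (33, "S"): 32.971458910000,
    (34, "S"): 33.967867011000,
    (79, "Br"): 78.918337600,
    (81, "Br"): 80.916288970,
    (35, "Cl"): 34.968852682108,
    (37, "Cl"): 36.965902573000,
}

PROTON_MASS = 1.00727646677
ELECTRON_MASS = 0.000548579909

_Key = Tuple[Optional[int], str]

# token: optional isotope prefix, element symbol, optional signed count
_TOKEN = re.compile(r"\s*(\d+)?([A-Z][a-z]?)(-?\d+)?")
# "D" is accepted as shorthand for deuterium
_DEUTERIUM = (2, "H")


class ElementalFormula:
    """A signed multiset of element (optionally isotope-labelled) counts.

    Supports ``+``, ``-``, unary ``-`` and scalar ``*``; zero counts are
    never stored, so two formulas compare equal iff they have identical
    non-zero counts.  Net-negative formulas are legal and encode losses.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Optional[Mapping[_Key, int]] = None):
        cleaned: Dict[_Key, int] = {}
        if counts:
            for key, n in counts.items():
                if not isinstance(n, int):
                    raise FormulaError(f"count for {key} must be an integer, got {n!r}")
                if n != 0:
                    cleaned[key] = n
        self._counts = cleaned

    # -- construction helpers ------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse formula text like ``"C1H4O1S1"``, ``"H-2"`` or ``"15N2"``.

        ``""`` and ``"(empty)"`` denote the empty formula.  Element symbols
        are case-sensitive; counts are optional signed integers (default 1).
        Whitespace between tokens is ignored, which disambiguates a count
        from a following isotope prefix (``"H1 15N2"``).
        """
        text = text.strip()
        if text in ("", "(empty)"):
            return cls()
        counts: Dict[_Key, int] = {}
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m or m.end() == m.start() or m.group(2) is None:
                raise FormulaError(f"malformed formula {text!r} at position {pos}")
            isotope_s, element, count_s = m.groups()
            isotope = int(isotope_s) if isotope_s else None
            count = int(count_s) if count_s else 1
            if element == "D" and isotope is None:
                isotope, element = _DEUTERIUM
            if isotope is not None:
                if (isotope, element) not in ISOTOPE_MASSES:
                    raise FormulaError(f"unknown isotope {isotope}{element} in {text!r}")
                key: _Key = (isotope, element)
            else:
                if element not in MONOISOTOPIC_MASSES:
                    raise FormulaError(f"unknown element {element!r} in {text!r}")
                key = (None, element)
            counts[key] = counts.get(key, 0) + count
            pos = m.end()
        return cls(counts)

    @classmethod
    def from_symbols(cls, **symbols: int) -> "ElementalFormula":
        """Build a formula from keyword counts, e.g. ``from_symbols(C=2, H=3)``."""
        return cls({(None, el): n for el, n in symbols.items()})

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for key, n in other._counts.items():
            counts[key] = counts.get(key, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for key, n in other._counts.items():
            counts[key] = counts.get(key, 0) - n
        return ElementalFormula(counts)

    def __neg__(self) -> "ElementalFormula":
        return ElementalFormula({k: -n for k, n in self._counts.items()})

    def __mul__(self, factor: int) -> "ElementalFormula":
        if not isinstance(factor, int):
            return NotImplemented
        return ElementalFormula({k: n * factor for k, n in self._counts.items()})

    __rmul__ = __mul__

    # -- queries -------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __iter__(self) -> Iterator[Tuple[_Key, int]]:
        return iter(self._counts.items())

    def __getitem__(self, key) -> int:
        if isinstance(key, str):
            key = (None, key)
        return self._counts.get(key, 0)

    def items(self) -> Iterable[Tuple[_Key, int]]:
        return self._counts.items()

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (linear in the counts)."""
        total = 0.0
        for (isotope, element), n in self._counts.items():
            if isotope is not None:
                total += n * ISOTOPE_MASSES[(isotope, element)]
            else:
                total += n * MONOISOTOPIC_MASSES[element]
        return total

    def with_isotope_substitution(
        self, substitutions: Mapping[str, int]
    ) -> "ElementalFormula":
        """Rewrite plain element keys to isotope-labelled ones.

        Implements ProForma global substitutions such as ``<15N>``: every
        unlabelled N becomes 15N.  Already-labelled entries are untouched.
        """
        if not substitutions:
            return self
        counts: Dict[_Key, int] = {}
        for (isotope, element), n in self._counts.items():
            if isotope is None and element in substitutions:
                key: _Key = (substitutions[element], element)
                if key not in ISOTOPE_MASSES:
                    raise FormulaError(f"unknown isotope {key[0]}{element}")
            else:
                key = (isotope, element)
            counts[key] = counts.get(key, 0) + n
        return ElementalFormula(counts)

    # -- text ----------------------------------------------------------------

    def text(self) -> str:
        """Canonical text: Hill-like order, explicit counts.

        Isotope-labelled tokens are preceded by a space so that the output
        re-parses unambiguously.
        """
        if not self._counts:
            return "(empty)"

        def sort_key(item):
            (isotope, element), _ = item
            rank = {"C": 0, "H": 1}.get(element, 2)
            return (rank, element, isotope or 0)

        parts = []
        for (isotope, element), n in sorted(self._counts.items(), key=sort_key):
            if isotope is not None:
                parts.append(f" {isotope}{element}{n}")
            else:
                parts.append(f"{element}{n}")
        return "".join(parts).strip()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.text()!r})"


# -- module-level convenience functions ---------------------------------------


def parse_formula(text: str) -> ElementalFormula:
    """Parse formula text; see :meth:`ElementalFormula.parse`."""
    return ElementalFormula.parse(text)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass of ``f`` in Da."""
    return f.mass


def mz(
    neutral_mass: float,
    charge: int,
    carrier_mass: float = PROTON_MASS,
) -> float:
    """m/z (Th) of a neutral species at the given charge.

    The default charge carrier is a proton; other carriers are supplied as
    their per-charge mass in Da.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * carrier_mass) / charge


# -- common small molecules ----------------------------------------------------

_F = ElementalFormula.from_symbols
WATER = _F(H=2, O=1)
AMMONIA = _F(N=1, H=3)
CARBON_MONOXIDE = _F(C=1, O=1)
HYDROGEN = _F(H=1)

#: Residue formulas (peptide-bond residues; free peptide = sum + H2O).
AMINO_ACIDS: Dict[str, ElementalFormula] = {
    "G": _F(C=2, H=3, N=1, O=1),
    "A": _F(C=3, H=5, N=1, O=1),
    "S": _F(C=3, H=5, N=1, O=2),
    "P": _F(C=5, H=7, N=1, O=1),
    "V": _F(C=5, H=9, N=1, O=1),
    "T": _F(C=4, H=7, N=1, O=2),
    "C": _F(C=3, H=5, N=1, O=1, S=1),
    "L": _F(C=6, H=11, N=1, O=1),
    "I": _F(C=6, H=11, N=1, O=1),
    "J": _F(C=6, H=11, N=1, O=1),  # Leu/Ile of unknown identity
    "N": _F(C=4, H=6, N=2, O=2),
    "D": _F(C=4, H=5, N=1, O=3),
    "Q": _F(C=5, H=8, N=2, O=2),
    "K": _F(C=6, H=12, N=2, O=1),
    "E": _F(C=5, H=7, N=1, O=3),
    "M": _F(C=5, H=9, N=1, O=1, S=1),
    "H": _F(C=6, H=7, N=3, O=1),
    "F": _F(C=9, H=9, N=1, O=1),
    "R": _F(C=6, H=12, N=4, O=1),
    "Y": _F(C=9, H=9, N=1, O=2),
    "W": _F(C=11, H=10, N=2, O=2),
    "U": _F(C=3, H=5, N=1, O=1, Se=1),  # selenocysteine
    "O": _F(C=12, H=19, N=3, O=2),  # pyrrolysine
}

#: Ambiguous one-letter codes that expand to two mass alternatives.
AMBIGUOUS_ALTERNATIVES: Dict[str, Tuple[str, str]] = {
    "B": ("N", "D"),
    "Z": ("Q", "E"),
}

#: Monosaccharide residue formulas (glycosidic-bond residues).
MONOSACCHARIDES: Dict[str, ElementalFormula] = {
    "Hex": _F(C=6, H=10, O=5),
    "HexNAc": _F(C=8, H=13, N=1, O=5),
    "dHex": _F(C=6, H=10, O=4),
    "NeuAc": _F(C=11, H=17, N=1, O=8),
    "NeuGc": _F(C=11, H=17, N=1, O=9),
    "Pen": _F(C=5, H=8, O=4),
    "HexA": _F(C=6, H=8, O=6),
    "HexN": _F(C=6, H=11, N=1, O=4),
}

#: Default secondary losses from the base oxonium ion, per monosaccharide kind.
DEFAULT_OXONIUM_LOSSES: Dict[str, Tuple[str, ...]] = {
    "HexNAc": ("H2O1", "H4O2", "C2H4O2", "C2H6O3"),
    "Hex": ("H2O1", "H4O2"),
    "NeuAc": ("H2O1",),
}
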
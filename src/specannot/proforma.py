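"""ProForma 2.0 peptidoform model (supported subset).

The grammar is handled by :mod:`pyteomics.proforma`; this module converts
the parsed tags into the package's own data model, resolving modification
names against a :class:`~specannot.modifications.ModificationRegistry` and
glycan notations against the monosaccharide table / a user structure file.
Constructs outside the supported subset (tagged intervals, fixed-modification
prefixes, non-proton adducts, ambiguity groups) raise a named
:class:`UnsupportedProFormaError` instead of being silently dropped.

Supported: residue mods by name/accession/bare mass, ``[Glycan:...]`` and
``[GNO:...]``, terminal mods, labile ``{...}`` mods, unknown-position
``[...]?`` mods, ``#XL`` cross-link pairs, ``+``-separated chimeras, ``/z``
charge and ``<15N>``-style global isotope substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from pyteomics import proforma as _pyproforma

from . import chem
from .chem import AMBIGUOUS_ALTERNATIVES, AMINO_ACIDS, ElementalFormula, WATER
from .glycans import GlycanComposition, GlycanTree
from .modifications import (
    AnyModification,
    BareMassModification,
    ModificationDefinition,
    ModificationRegistry,
    UnknownModificationError,
    resolve_modification,
)

__all__ = [
    "ProFormaParseError",
    "UnsupportedProFormaError",
    "ModAttachment",
    "GlycanAttachment",
    "CrossLinkAttachment",
    "CrossLink",
    "Peptidoform",
    "CompoundPeptidoform",
    "parse_proforma",
    "canonical_string",
    "peptidoform_neutral_mass",
]


class ProFormaParseError(ValueError):
    """Malformed or semantically invalid ProForma text."""


class UnsupportedProFormaError(ProFormaParseError):
    """Valid ProForma using a construct outside the supported subset."""


@dataclass(frozen=True)
class ModAttachment:
    """A located (or terminal/labile/unknown-position) modification."""

    definition: AnyModification

    @property
    def mass(self) -> float:
        return self.definition.mass

    def proforma_text(self) -> str:
        if isinstance(self.definition, BareMassModification):
            return f"[{self.definition.bare_mass:+g}]"
        return f"[{self.definition.name}]"


@dataclass(frozen=True)
class GlycanAttachment:
    """A glycan modification, by composition and optionally by topology."""

    composition: GlycanComposition
    tree: Optional[GlycanTree] = None
    gno_id: Optional[str] = None

    @property
    def mass(self) -> float:
        return self.composition.formula().mass

    @property
    def formula(self) -> ElementalFormula:
        return self.composition.formula()

    def proforma_text(self) -> str:
        if self.gno_id:
            return f"[GNO:{self.gno_id}]"
        return f"[Glycan:{self.composition.text()}]"


@dataclass(frozen=True)
class CrossLinkAttachment:
    """One endpoint of a named cross-link; the defining side carries the linker."""

    name: str
    definition: Optional[ModificationDefinition] = None

    def proforma_text(self) -> str:
        if self.definition is not None:
            return f"[XL:{self.definition.name}#{self.name}]"
        return f"[#{self.name}]"


Attachment = Union[ModAttachment, GlycanAttachment, CrossLinkAttachment]


@dataclass(frozen=True)
class CrossLink:
    """A resolved cross-link: its linker chemistry and its two sites."""

    name: str
    definition: ModificationDefinition
    sites: Tuple[Tuple[int, int], Tuple[int, int]]  # (peptidoform idx, residue idx)

    @property
    def intra(self) -> bool:
        return self.sites[0][0] == self.sites[1][0]


@dataclass
class Peptidoform:
    """One peptidoform: residues, attached modifications, charge, isotopes."""

    sequence: str
    residue_mods: List[List[Attachment]]
    n_term: List[Attachment] = field(default_factory=list)
    c_term: List[Attachment] = field(default_factory=list)
    labile: List[Attachment] = field(default_factory=list)
    unknown_position: List[Attachment] = field(default_factory=list)
    charge: Optional[int] = None
    #: global isotope substitutions, element symbol -> mass number
    isotopes: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ProFormaParseError("empty peptidoform sequence")
        if len(self.residue_mods) != len(self.sequence):
            raise ValueError("residue_mods length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    # -- mass bookkeeping ----------------------------------------------------

    def residue_alternatives(self, i: int) -> List[Tuple[ElementalFormula, str]]:
        """Formula alternatives for residue ``i`` (B/Z expand to two)."""
        aa = self.sequence[i]
        if aa in AMINO_ACIDS:
            return [(AMINO_ACIDS[aa], aa)]
        if aa in AMBIGUOUS_ALTERNATIVES:
            return [(AMINO_ACIDS[alt], alt) for alt in AMBIGUOUS_ALTERNATIVES[aa]]
        if aa == "X":
            if any(isinstance(m, ModAttachment) for m in self.residue_mods[i]):
                return [(ElementalFormula(), "X")]
            raise ProFormaParseError(
                f"residue X at position {i + 1} carries no mass modification"
            )
        raise ProFormaParseError(f"unknown residue {aa!r}")

    def _attachment_mass(self, att: Attachment, include_crosslinks: bool) -> float:
        if isinstance(att, CrossLinkAttachment):
            if include_crosslinks and att.definition is not None:
                return att.definition.mass
            return 0.0
        return att.mass

    def neutral_masses(
        self, include_labile: bool = False, include_crosslinks: bool = False
    ) -> List[float]:
        """All neutral-mass alternatives (sorted, deduplicated).

        Labile mods are excluded by default; the intact species is obtained
        with ``include_labile=True``.  Cross-linker deltas and partner masses
        belong to the complex, not the single chain, and are excluded unless
        requested.
        """
        masses = [0.0]
        for i in range(len(self.sequence)):
            alts = self.residue_alternatives(i)
            masses = [m + alt[0].with_isotope_substitution(self.isotopes).mass
                      for m in masses for alt in alts]
            mod_mass = sum(
                self._attachment_mass(a, include_crosslinks) for a in self.residue_mods[i]
            )
            masses = [m + mod_mass for m in masses]
        fixed = WATER.with_isotope_substitution(self.isotopes).mass
        fixed += sum(self._attachment_mass(a, include_crosslinks)
                     for a in self.n_term + self.c_term + self.unknown_position)
        if include_labile:
            fixed += sum(self._attachment_mass(a, include_crosslinks) for a in self.labile)
        return sorted({round(m + fixed, 9) for m in masses})

    @property
    def neutral_mass(self) -> float:
        """The single neutral mass; first alternative when ambiguous."""
        return self.neutral_masses()[0]

    def proforma_text(self) -> str:
        parts: List[str] = []
        if self.isotopes:
            for el, a in sorted(self.isotopes.items()):
                parts.append(f"<{a}{el}>")
        for att in self.unknown_position:
            parts.append(att.proforma_text() + "?")
        for att in self.labile:
            parts.append("{" + att.proforma_text()[1:-1] + "}")
        if self.n_term:
            parts.append("".join(a.proforma_text() for a in self.n_term) + "-")
        for aa, mods in zip(self.sequence, self.residue_mods):
            parts.append(aa + "".join(a.proforma_text() for a in mods))
        if self.c_term:
            parts.append("-" + "".join(a.proforma_text() for a in self.c_term))
        if self.charge is not None:
            parts.append(f"/{self.charge}")
        return "".join(parts)


@dataclass
class CompoundPeptidoform:
    """One or more peptidoforms: chimeric members and/or cross-linked partners."""

    peptidoforms: List[Peptidoform]
    crosslinks: Dict[str, CrossLink] = field(default_factory=dict)

    def __post_init__(self):
        if not self.peptidoforms:
            raise ProFormaParseError("compound peptidoform must have at least one member")

    def __len__(self) -> int:
        return len(self.peptidoforms)

    @property
    def precursor_charge(self) -> Optional[int]:
        charges = [p.charge for p in self.peptidoforms if p.charge is not None]
        return max(charges) if charges else None

    def proforma_text(self) -> str:
        return "+".join(p.proforma_text() for p in self.peptidoforms)


# -- parsing -------------------------------------------------------------------


def _convert_tag(
    tag,
    registry: ModificationRegistry,
    glycan_structures: Optional[Mapping[str, GlycanTree]],
) -> Attachment:
    name = type(tag).__name__
    group = getattr(tag, "group_id", None)
    if group is not None:
        return _convert_crosslink_tag(tag, group, registry)
    if name == "MassModification":
        return ModAttachment(BareMassModification(float(tag.value)))
    if name == "GlycanModification":
        comp = GlycanComposition.from_mapping(dict(tag.monosaccharides))
        comp.formula()  # validates kinds against the table
        return GlycanAttachment(comp)
    if name == "GNOmeModification":
        gno_id = str(tag.value)
        if not glycan_structures or gno_id not in glycan_structures:
            raise ProFormaParseError(
                f"GNO id {gno_id!r} not found in the supplied glycan-structure file"
            )
        tree = glycan_structures[gno_id]
        return GlycanAttachment(tree.composition(), tree=tree, gno_id=gno_id)
    if name in ("GenericModification", "UnimodModification"):
        token = str(tag.value)
        if name == "UnimodModification":
            try:
                return ModAttachment(registry.get(token))
            except UnknownModificationError:
                raise UnknownModificationError(f"Unimod:{token}") from None
        return ModAttachment(resolve_modification(token, registry))
    raise UnsupportedProFormaError(f"unsupported ProForma tag {name} ({tag})")


def _convert_crosslink_tag(tag, group: str, registry: ModificationRegistry) -> Attachment:
    xl_name = group.lstrip("#")
    if not xl_name.upper().startswith("XL"):
        raise UnsupportedProFormaError(
            f"ambiguity groups ({group}) are not supported; only #XL cross-links"
        )
    if type(tag).__name__ == "PositionLabelTag":
        return CrossLinkAttachment(xl_name)
    token = str(tag.value)
    if token.startswith("XL:"):
        token = token[3:]
    definition = registry.get(token)
    if not definition.linker:
        raise ProFormaParseError(f"modification {definition.name!r} cannot bridge two sites")
    return CrossLinkAttachment(xl_name, definition)


def _convert_member(
    parsed,
    registry: ModificationRegistry,
    glycan_structures: Optional[Mapping[str, GlycanTree]],
) -> Peptidoform:
    props = parsed.properties
    if props.get("intervals"):
        raise UnsupportedProFormaError("tagged intervals (ranged modifications)")
    if props.get("fixed_modifications"):
        raise UnsupportedProFormaError("fixed-modification prefixes (<[...]@X>)")
    charge = None
    cs = props.get("charge_state")
    if cs is not None:
        for adduct in cs.adducts or ():
            if adduct.name != "H" or adduct.charge != 1:
                raise UnsupportedProFormaError(f"non-proton adduct {adduct}")
        charge = int(cs.charge)
    isotopes: Dict[str, int] = {}
    for iso in props.get("isotopes") or ():
        text = str(iso.isotope)  # e.g. "15N" or "D"
        if text == "D":
            isotopes["H"] = 2
        else:
            num = "".join(c for c in text if c.isdigit())
            el = "".join(c for c in text if not c.isdigit())
            isotopes[el] = int(num)

    def convert_list(tags) -> List[Attachment]:
        return [_convert_tag(t, registry, glycan_structures) for t in (tags or ())]

    sequence = "".join(aa for aa, _ in parsed.sequence)
    if not sequence:
        raise ProFormaParseError("empty peptidoform sequence")
    residue_mods = [convert_list(mods) for _, mods in parsed.sequence]
    return Peptidoform(
        sequence=sequence,
        residue_mods=residue_mods,
        n_term=convert_list(props.get("n_term")),
        c_term=convert_list(props.get("c_term")),
        labile=convert_list(props.get("labile_modifications")),
        unknown_position=convert_list(props.get("unlocalized_modifications")),
        charge=charge,
        isotopes=isotopes,
    )


def _resolve_crosslinks(peptidoforms: List[Peptidoform]) -> Dict[str, CrossLink]:
    sites: Dict[str, List[Tuple[int, int, Optional[ModificationDefinition]]]] = {}
    for p_idx, pep in enumerate(peptidoforms):
        for r_idx, mods in enumerate(pep.residue_mods):
            for att in mods:
                if isinstance(att, CrossLinkAttachment):
                    sites.setdefault(att.name, []).append((p_idx, r_idx, att.definition))
    links: Dict[str, CrossLink] = {}
    for name, entries in sites.items():
        if len(entries) != 2:
            raise ProFormaParseError(
                f"cross-link {name!r} referenced {len(entries)} time(s); expected exactly 2"
            )
        definitions = [d for _, _, d in entries if d is not None]
        if len(definitions) != 1:
            raise ProFormaParseError(
                f"cross-link {name!r} must carry exactly one linker definition"
            )
        links[name] = CrossLink(
            name=name,
            definition=definitions[0],
            sites=((entries[0][0], entries[0][1]), (entries[1][0], entries[1][1])),
        )
    return links


def parse_proforma(
    text: str,
    registry: ModificationRegistry,
    glycan_structures: Optional[Mapping[str, GlycanTree]] = None,
) -> CompoundPeptidoform:
    """Parse ProForma text (supported subset) into a :class:`CompoundPeptidoform`."""
    if not text or not text.strip():
        raise ProFormaParseError("empty ProForma string")
    try:
        parsed = _pyproforma.ProForma.parse(text.strip(), chimeric=True)
    except UnicodeDecodeError:
        raise
    except Exception as exc:  # pyteomics raises its own error hierarchy
        raise ProFormaParseError(f"invalid ProForma {text!r}: {exc}") from exc
    members = list(parsed.peptides) if isinstance(parsed, _pyproforma.Chimeric) else [parsed]
    peptidoforms = [_convert_member(m, registry, glycan_structures) for m in members]
    crosslinks = _resolve_crosslinks(peptidoforms)
    return CompoundPeptidoform(peptidoforms, crosslinks)


def canonical_string(cp: CompoundPeptidoform) -> str:
    """Canonical ProForma text; parsing it back reproduces the model."""
    return cp.proforma_text()


def peptidoform_neutral_mass(p: Peptidoform, include_labile: bool = False) -> List[float]:
    """Neutral-mass alternative(s) of one peptidoform chain in Da."""
    return p.neutral_masses(include_labile=include_labile)
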
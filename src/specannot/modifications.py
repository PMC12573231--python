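"""Modification registry.

Definitions carry an elemental delta (or a bare mass), placement targets,
neutral losses, diagnostic ions and — for cross-linkers — breakage rules
describing what each side of a cleaved link retains.  A minimal bundled set
covers the common cases (oxidation, phosphorylation, carbamidomethylation,
acetylation, deamidation, pyroglutamate, DSS, disulfide); further
definitions load from user JSON files that share one schema with the
bundled file.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .chem import ElementalFormula, FormulaError, parse_formula

__all__ = [
    "BreakageRule",
    "ModificationDefinition",
    "ModificationRegistry",
    "UnknownModificationError",
    "RegistryError",
    "load_modification_registry",
    "resolve_modification",
]


class UnknownModificationError(KeyError):
    """A modification token that no registry entry (or mass syntax) matches."""


class RegistryError(ValueError):
    """Malformed registry file (duplicate names, bad formulas, ...)."""


@dataclass(frozen=True)
class BreakageRule:
    """Deltas applied to the two sides of a cleaved cross-link.

    ``retained`` is added to the fragment that is being generated;
    ``partner`` to the complementary side.  Both are relative to the
    unmodified residues, i.e. they replace the linker delta entirely.
    """

    retained: ElementalFormula
    partner: ElementalFormula

    @property
    def total(self) -> ElementalFormula:
        return self.retained + self.partner

    def label(self) -> str:
        return f"{self.retained.text()}:{self.partner.text()}"


@dataclass(frozen=True)
class ModificationDefinition:
    name: str
    aliases: Tuple[str, ...] = ()
    formula: Optional[ElementalFormula] = None
    bare_mass: Optional[float] = None
    targets: Tuple[str, ...] = ()
    #: (loss formula, residue restriction or None)
    neutral_losses: Tuple[Tuple[ElementalFormula, Optional[Tuple[str, ...]]], ...] = ()
    diagnostic_ions: Tuple[ElementalFormula, ...] = ()
    breakage_rules: Tuple[BreakageRule, ...] = ()
    linker: bool = False

    def __post_init__(self):
        if self.formula is None and self.bare_mass is None:
            raise RegistryError(f"modification {self.name!r} has neither formula nor mass")
        if self.breakage_rules and not self.linker:
            raise RegistryError(
                f"modification {self.name!r} has breakage rules but is not a linker"
            )

    @property
    def mass(self) -> float:
        if self.formula is not None:
            return self.formula.mass
        return float(self.bare_mass)  # type: ignore[arg-type]

    def losses_for_residue(self, residue: Optional[str]) -> List[ElementalFormula]:
        """Neutral losses applicable when the mod sits on ``residue``."""
        out = []
        for loss, restriction in self.neutral_losses:
            if restriction is None or residue is None or residue in restriction:
                out.append(loss)
        return out


@dataclass(frozen=True)
class BareMassModification:
    """A ProForma ``[+mass]`` tag: a delta with no formula, losses or ions."""

    bare_mass: float
    name: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.name:
            object.__setattr__(self, "name", f"{self.bare_mass:+.4f}")

    @property
    def mass(self) -> float:
        return self.bare_mass

    formula = None
    neutral_losses: Tuple = ()
    diagnostic_ions: Tuple = ()
    breakage_rules: Tuple = ()
    linker = False

    def losses_for_residue(self, residue):
        return []


AnyModification = Union[ModificationDefinition, BareMassModification]

_MASS_TOKEN = re.compile(r"^[+-]\d+(\.\d+)?$")


class ModificationRegistry:
    """Name/alias-indexed (case-insensitive) modification lookup."""

    def __init__(self, definitions: Sequence[ModificationDefinition] = ()):
        self._by_name: Dict[str, ModificationDefinition] = {}
        for d in definitions:
            self.add(d)

    def add(self, definition: ModificationDefinition) -> None:
        for key in (definition.name, *definition.aliases):
            self._by_name[key.lower()] = definition

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._by_name

    def get(self, name: str) -> ModificationDefinition:
        try:
            return self._by_name[name.lower()]
        except KeyError:
            raise UnknownModificationError(name) from None

    def names(self) -> List[str]:
        return sorted({d.name for d in self._by_name.values()})

    def linkers(self) -> List[ModificationDefinition]:
        return [self._by_name[n.lower()] for n in self.names() if self._by_name[n.lower()].linker]


def _parse_loss_entry(entry) -> Tuple[ElementalFormula, Optional[Tuple[str, ...]]]:
    if isinstance(entry, str):
        return parse_formula(entry), None
    return parse_formula(entry["formula"]), tuple(entry.get("targets", ())) or None


def _definition_from_dict(raw: dict) -> ModificationDefinition:
    try:
        formula = parse_formula(raw["formula"]) if "formula" in raw else None
    except FormulaError as exc:
        raise RegistryError(f"modification {raw.get('name')!r}: {exc}") from exc
    breakage = tuple(
        BreakageRule(parse_formula(b["retained"]), parse_formula(b["partner"]))
        for b in raw.get("breakage", ())
    )
    return ModificationDefinition(
        name=raw["name"],
        aliases=tuple(raw.get("aliases", ())),
        formula=formula,
        bare_mass=raw.get("mass"),
        targets=tuple(raw.get("targets", ())),
        neutral_losses=tuple(_parse_loss_entry(e) for e in raw.get("neutral_losses", ())),
        diagnostic_ions=tuple(parse_formula(f) for f in raw.get("diagnostic_ions", ())),
        breakage_rules=breakage,
        linker=bool(raw.get("linker", False)),
    )


def _load_file(path) -> List[ModificationDefinition]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise RegistryError(f"{path}: expected a JSON array of definitions")
    defs = [_definition_from_dict(d) for d in raw]
    names = [d.name.lower() for d in defs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise RegistryError(f"{path}: duplicate modification names {sorted(dupes)}")
    return defs


def bundled_definitions() -> List[ModificationDefinition]:
    with resources.files("specannot.data").joinpath("modifications.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return [_definition_from_dict(d) for d in json.load(fh)]


def load_modification_registry(
    paths: Sequence[Union[str, Path]] = (),
) -> ModificationRegistry:
    """Build a registry from the bundled defaults plus user JSON files.

    Later files override earlier names; user files override the bundled set.
    """
    registry = ModificationRegistry(bundled_definitions())
    for path in paths:
        for definition in _load_file(path):
            registry.add(definition)
    return registry


def resolve_modification(token: str, registry: ModificationRegistry) -> AnyModification:
    """Resolve a name, accession alias, or ``+mass`` token.

    Bare-mass tokens never touch the registry; anything else must exist.
    """
    token = token.strip()
    if _MASS_TOKEN.match(token):
        return BareMassModification(float(token))
    return registry.get(token)
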
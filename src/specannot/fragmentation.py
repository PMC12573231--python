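"""Theoretical fragment generation.

Given a :class:`~specannot.proforma.CompoundPeptidoform` and a
:class:`FragmentationModel`, produce every theoretical fragment the model
allows: backbone series (a/b/c from the N terminus, x/y/z from the C
terminus), satellite series (d/w from side-chain cleavage at the C-beta
atom, v from complete side-chain loss), immonium ions, precursor species,
modification diagnostic ions and glycan B/Y/oxonium ions.

Neutral masses are assembled from elemental formulas throughout (bare-mass
modifications contribute a separate scalar term), so complementarity
identities such as ``b_i + y_{n-i} = M`` hold to float precision by
construction.

Backbone conventions (prefix_i = N-terminal residues 1..i + mods,
suffix_j = C-terminal residues + mods + H2O)::

    a_i = prefix_i - CO        x_j = suffix_j + CO - H2
    b_i = prefix_i             y_j = suffix_j
    c_i = prefix_i + NH3       z_j = suffix_j - NH3   (z-dot = z + H)

Satellite hydrogen bookkeeping: d_i = a_i + H - distal(residue i) (the a+1
radical loses the distal group as a radical); w_j = z-dot_j - distal;
v_j replaces the complete side chain with H (v_j = y_j - sidechain + H,
the glycine-equivalent y ion).

Cross-linked residues: a fragment spanning one endpoint of a link carries,
as variants, the intact link (linker delta plus everything attached through
it) and one variant per breakage rule of the linker (the rule's retained
delta only).  Cleavage positions inside a cyclic region (the two sides of
the cut still connected through intact links) yield no intact fragment.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .chem import (
    AMMONIA,
    CARBON_MONOXIDE,
    HYDROGEN,
    PROTON_MASS,
    WATER,
    ElementalFormula,
    mz as _mz,
    parse_formula,
)
from .glycans import (
    GlycanFragment,
    composition_fragments,
    glycan_diagnostic_ions,
    topology_fragments,
)
from .modifications import BareMassModification, ModificationDefinition
from .proforma import (
    CompoundPeptidoform,
    CrossLink,
    CrossLinkAttachment,
    GlycanAttachment,
    ModAttachment,
    Peptidoform,
)

__all__ = [
    "SeriesSettings",
    "FragmentationModel",
    "TheoreticalFragment",
    "FragmentationError",
    "VariantExplosionError",
    "get_model",
    "MODEL_PRESETS",
    "backbone_fragments",
    "satellite_fragments",
    "immonium_fragments",
    "precursor_fragments",
    "generate_fragments",
]

_EMPTY = ElementalFormula()
_F = ElementalFormula.from_symbols

N_TERMINAL_SERIES = ("a", "b", "c", "d")
C_TERMINAL_SERIES = ("x", "y", "z", "v", "w")
BACKBONE_SERIES = ("a", "b", "c", "x", "y", "z")
SATELLITE_SERIES = ("d", "v", "w")

_BACKBONE_DELTA: Dict[str, ElementalFormula] = {
    "a": -CARBON_MONOXIDE,
    "b": _EMPTY,
    "c": AMMONIA,
    "x": CARBON_MONOXIDE - _F(H=2),
    "y": _EMPTY,
    "z": -AMMONIA,
}

#: Default C-beta distal groups for d/w ions (lost as radicals).
DEFAULT_DISTAL_GROUPS: Dict[str, Tuple[str, ...]] = {
    "V": ("C1H3",),
    "I": ("C1H3", "C2H5"),
    "L": ("C3H7",),
    "T": ("C1H3", "O1H1"),
}

#: Residues with no (usable) side chain for v ions.
_NO_V_IONS = frozenset("GP")

#: Backbone part of a residue; side chain = residue formula - this.
_RESIDUE_BACKBONE = _F(C=2, H=2, N=1, O=1)

MAX_VARIANTS = 512


class FragmentationError(ValueError):
    pass


class VariantExplosionError(FragmentationError):
    """More ambiguous-placement mass variants than the supported cap."""


@dataclass(frozen=True)
class SeriesSettings:
    """Per-series generation settings."""

    enabled: bool = False
    losses: Tuple[ElementalFormula, ...] = ()
    max_losses: int = 1
    #: absolute (lo, hi) charge range, or None = 1..precursor charge
    charges: Optional[Tuple[int, int]] = None
    #: hydrogen offsets; e.g. (1,) for z-dot only, (0, 1) for z and z-dot
    h_variants: Tuple[int, ...] = (0,)

    def __post_init__(self):
        if self.enabled and self.charges is not None and self.charges[0] > self.charges[1]:
            raise FragmentationError(f"empty charge range {self.charges}")

    def charge_list(self, precursor_charge: Optional[int]) -> List[int]:
        if self.charges is not None:
            return list(range(self.charges[0], self.charges[1] + 1))
        top = max(1, (precursor_charge or 1))
        return list(range(1, top + 1))

    def to_dict(self) -> dict:
        return {
            "enabled": self.enabled,
            "losses": [f.text() for f in self.losses],
            "max_losses": self.max_losses,
            "charges": list(self.charges) if self.charges else None,
            "variants": list(self.h_variants),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "SeriesSettings":
        return cls(
            enabled=raw.get("enabled", False),
            losses=tuple(parse_formula(t) for t in raw.get("losses", ())),
            max_losses=raw.get("max_losses", 1),
            charges=tuple(raw["charges"]) if raw.get("charges") else None,
            h_variants=tuple(raw.get("variants", (0,))),
        )


@dataclass(frozen=True)
class FragmentationModel:
    """Full description of which theoretical fragments to generate."""

    name: str = "custom"
    series: Mapping[str, SeriesSettings] = field(default_factory=dict)
    immonium: bool = False
    diagnostic_ions: bool = True
    precursor_losses: Tuple[ElementalFormula, ...] = ()
    precursor_max_losses: int = 1
    #: explicit precursor charge list, or None = 1..precursor charge
    precursor_charges: Optional[Tuple[int, ...]] = None
    glycan_enabled: bool = False
    glycan_min_size: int = 1
    glycan_max_size: Optional[int] = None
    glycan_max_breaks: Optional[int] = None
    glycan_b_charges: Tuple[int, ...] = (1, 2)
    #: per-residue side-chain losses pooled into fragment/precursor losses
    sidechain_losses: Mapping[str, Tuple[ElementalFormula, ...]] = field(default_factory=dict)
    distal_groups: Mapping[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DISTAL_GROUPS)
    )

    def series_settings(self, kind: str) -> SeriesSettings:
        return self.series.get(kind, SeriesSettings())

    def enabled_series(self) -> List[str]:
        return [k for k in (*BACKBONE_SERIES, *SATELLITE_SERIES)
                if self.series_settings(k).enabled]

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "series": {k: s.to_dict() for k, s in self.series.items()},
            "immonium": self.immonium,
            "diagnostic_ions": self.diagnostic_ions,
            "precursor": {
                "losses": [f.text() for f in self.precursor_losses],
                "max_losses": self.precursor_max_losses,
                "charges": list(self.precursor_charges) if self.precursor_charges else None,
            },
            "glycan": {
                "enabled": self.glycan_enabled,
                "min_size": self.glycan_min_size,
                "max_size": self.glycan_max_size,
                "max_breaks": self.glycan_max_breaks,
                "b_charges": list(self.glycan_b_charges),
            },
            "sidechain_losses": {
                aa: [f.text() for f in fs] for aa, fs in self.sidechain_losses.items()
            },
            "distal_groups": {aa: list(gs) for aa, gs in self.distal_groups.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, raw: dict) -> "FragmentationModel":
        prec = raw.get("precursor", {})
        gly = raw.get("glycan", {})
        return cls(
            name=raw.get("name", "custom"),
            series={k: SeriesSettings.from_dict(s) for k, s in raw.get("series", {}).items()},
            immonium=raw.get("immonium", False),
            diagnostic_ions=raw.get("diagnostic_ions", True),
            precursor_losses=tuple(parse_formula(t) for t in prec.get("losses", ())),
            precursor_max_losses=prec.get("max_losses", 1),
            precursor_charges=tuple(prec["charges"]) if prec.get("charges") else None,
            glycan_enabled=gly.get("enabled", False),
            glycan_min_size=gly.get("min_size", 1),
            glycan_max_size=gly.get("max_size"),
            glycan_max_breaks=gly.get("max_breaks"),
            glycan_b_charges=tuple(gly.get("b_charges", (1, 2))),
            sidechain_losses={
                aa: tuple(parse_formula(t) for t in fs)
                for aa, fs in raw.get("sidechain_losses", {}).items()
            },
            distal_groups={aa: tuple(gs) for aa, gs in raw.get("distal_groups", {}).items()}
            or dict(DEFAULT_DISTAL_GROUPS),
        )

    @classmethod
    def from_json(cls, path) -> "FragmentationModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _series(enabled: Sequence[str], losses: Mapping[str, Sequence[str]] = (),
            h_variants: Mapping[str, Tuple[int, ...]] = ()) -> Dict[str, SeriesSettings]:
    losses = dict(losses or {})
    h_variants = dict(h_variants or {})
    out = {}
    for kind in enabled:
        out[kind] = SeriesSettings(
            enabled=True,
            losses=tuple(parse_formula(t) for t in losses.get(kind, ())),
            h_variants=h_variants.get(kind, (0,)),
        )
    return out


_WATER_AMMONIA = {"H2O1", "N1H3"}
_ELECTRON_LOSSES = {"C1H1O2", "C2H3O2"}  # -CHO2 and -C2H3O2 in electron-based modes


def _preset(name: str) -> FragmentationModel:
    wa = tuple(sorted(_WATER_AMMONIA))
    el = tuple(sorted(_WATER_AMMONIA | _ELECTRON_LOSSES))
    if name in ("cid", "hcd", "cid_hcd"):
        return FragmentationModel(
            name="cid_hcd",
            series=_series("aby", {k: wa for k in "aby"}),
            immonium=True,
            precursor_losses=(parse_formula("H2O1"), parse_formula("N1H3")),
            glycan_enabled=True,
        )
    if name == "etd":
        return FragmentationModel(
            name="etd",
            series=_series("cz", {"c": ("N1H3",), "z": ("N1H3",)}, {"z": (1,)}),
        )
    if name in ("ethcd", "etcad"):
        return FragmentationModel(
            name=name,
            series=_series("bcyz", {k: el for k in "bcyz"}, {"z": (1,)}),
            immonium=True,
            precursor_losses=(parse_formula("H2O1"), parse_formula("N1H3")),
            glycan_enabled=True,
        )
    if name in ("ead", "eacid"):
        return FragmentationModel(
            name=name,
            series=_series("abcyzwd", {k: el for k in "abcyz"}, {"z": (1,)}),
            immonium=True,
            glycan_enabled=True,
        )
    if name == "uvpd":
        return FragmentationModel(
            name="uvpd",
            series=_series("abcxyzdvw", {k: wa for k in "abcxyz"}),
            immonium=True,
        )
    if name in ("bare", "none"):
        return FragmentationModel(name="bare", series=_series("bcyz"), diagnostic_ions=False)
    if name == "all":
        return FragmentationModel(
            name="all",
            series=_series("abcxyzdvw", {k: el for k in "abcxyz"}, {"z": (0, 1)}),
            immonium=True,
            precursor_losses=(parse_formula("H2O1"), parse_formula("N1H3")),
            glycan_enabled=True,
        )
    raise FragmentationError(f"unknown fragmentation model preset {name!r}")


MODEL_PRESETS = ("cid_hcd", "etd", "ethcd", "etcad", "ead", "eacid", "uvpd", "bare", "all")


def get_model(name: str) -> FragmentationModel:
    """Look up a named preset (``ethcd``, ``cid_hcd``, ...); case-insensitive."""
    return _preset(name.lower())


@dataclass(frozen=True)
class TheoreticalFragment:
    """One theoretical ion: typed, charged, with a fully assembled mass."""

    kind: str  # a,b,c,x,y,z,d,v,w | immonium | precursor | diagnostic | glycan_B | glycan_Y
    peptidoform_index: int
    position: Optional[int]  # series index (1-based), None for non-positional ions
    charge: int
    neutral_mass: float
    formula: Optional[ElementalFormula] = None
    losses: Tuple[str, ...] = ()
    variant: str = ""
    label: str = ""

    @property
    def mz(self) -> float:
        return _mz(self.neutral_mass, self.charge)

    @property
    def is_n_terminal(self) -> bool:
        return self.kind in N_TERMINAL_SERIES

    @property
    def is_c_terminal(self) -> bool:
        return self.kind in C_TERMINAL_SERIES

    def covered_residue(self, length: int) -> Optional[int]:
        """1-based residue supported by this ion, per the coverage rule."""
        if self.position is None:
            return None
        if self.is_n_terminal:
            return self.position
        if self.is_c_terminal:
            return length - self.position + 1
        return None

    def identity(self) -> tuple:
        """Distinctness key: (kind, peptidoform, position, variant, losses, charge)."""
        return (self.kind, self.peptidoform_index, self.position, self.variant,
                tuple(sorted(self.losses)), self.charge)


# -- internal variant bookkeeping ---------------------------------------------


@dataclass(frozen=True)
class _Mass:
    """A (formula, scalar extra) pair with an ambiguity/variant tag trail."""

    formula: ElementalFormula = _EMPTY
    extra: float = 0.0
    tags: Tuple[str, ...] = ()

    def add(self, formula: ElementalFormula = _EMPTY, extra: float = 0.0,
            tag: Optional[str] = None) -> "_Mass":
        tags = self.tags + (tag,) if tag else self.tags
        return _Mass(self.formula + formula, self.extra + extra, tags)

    def mass(self, isotopes: Mapping[str, int]) -> float:
        return self.formula.with_isotope_substitution(isotopes).mass + self.extra


def _attachment_contribution(att, residue: Optional[str]) -> Tuple[ElementalFormula, float, Optional[str]]:
    """(formula, extra mass, tag) contributed by a located attachment."""
    if isinstance(att, ModAttachment):
        d = att.definition
        if isinstance(d, BareMassModification):
            return _EMPTY, d.bare_mass, None
        if d.formula is not None:
            return d.formula, 0.0, None
        return _EMPTY, d.mass, None
    if isinstance(att, GlycanAttachment):
        return att.formula, 0.0, None
    raise TypeError(att)


def _cap(variants: List[_Mass]) -> List[_Mass]:
    if len(variants) > MAX_VARIANTS:
        raise VariantExplosionError(
            f"{len(variants)} mass variants at one position exceeds the cap of {MAX_VARIANTS}"
        )
    return variants


class _PeptidoformContext:
    """Precomputed per-residue mass variants and loss/cross-link inventory."""

    def __init__(self, cp: CompoundPeptidoform, p_idx: int, model: FragmentationModel):
        self.cp = cp
        self.p_idx = p_idx
        self.pep = cp.peptidoforms[p_idx]
        self.model = model
        n = len(self.pep)
        #: per residue: list of (_Mass) alternatives incl. located mods (no labile, no XL)
        self.residue_masses: List[List[_Mass]] = []
        #: per residue: applicable modification neutral losses
        self.residue_mod_losses: List[List[ElementalFormula]] = []
        for i in range(n):
            alts = []
            for formula, tag_aa in self.pep.residue_alternatives(i):
                m = _Mass(formula, 0.0,
                          (f"{tag_aa}@{i + 1}",) if tag_aa != self.pep.sequence[i] else ())
                for att in self.pep.residue_mods[i]:
                    if isinstance(att, CrossLinkAttachment):
                        continue
                    df, de, _ = _attachment_contribution(att, self.pep.sequence[i])
                    m = m.add(df, de)
                alts.append(m)
            self.residue_masses.append(_cap(alts))
            losses: List[ElementalFormula] = []
            for att in self.pep.residue_mods[i]:
                if isinstance(att, ModAttachment) and not isinstance(
                    att.definition, BareMassModification
                ):
                    losses.extend(att.definition.losses_for_residue(self.pep.sequence[i]))
            losses.extend(model.sidechain_losses.get(self.pep.sequence[i], ()))
            self.residue_mod_losses.append(losses)
        self.n_term_mass = self._terminal_mass(self.pep.n_term)
        self.c_term_mass = self._terminal_mass(self.pep.c_term)
        #: optional-placement extras applied to every fragment as variants
        self.unknown_mods = [
            _attachment_contribution(a, None)[:2] + (f"?{_attachment_name(a)}",)
            for a in self.pep.unknown_position
        ]

    @staticmethod
    def _terminal_mass(attachments) -> _Mass:
        m = _Mass()
        for att in attachments:
            if isinstance(att, CrossLinkAttachment):
                continue
            df, de, _ = _attachment_contribution(att, None)
            m = m.add(df, de)
        return m

    # -- stretch accumulation -------------------------------------------------

    def stretch_masses(self, lo: int, hi: int) -> List[_Mass]:
        """Mass variants for residues [lo, hi) (0-based), mods included."""
        variants = [_Mass()]
        for i in range(lo, hi):
            variants = _cap([v.add(alt.formula, alt.extra) if not alt.tags
                             else replace(v.add(alt.formula, alt.extra),
                                          tags=v.tags + alt.tags)
                             for v in variants for alt in self.residue_masses[i]])
        return variants

    def stretch_losses(self, lo: int, hi: int) -> List[ElementalFormula]:
        out: List[ElementalFormula] = []
        for i in range(lo, hi):
            out.extend(self.residue_mod_losses[i])
        return out


def _attachment_name(att) -> str:
    if isinstance(att, ModAttachment):
        return att.definition.name
    if isinstance(att, GlycanAttachment):
        return f"Glycan:{att.composition.text()}"
    return str(att)


# -- cross-link resolution ------------------------------------------------------


def _chain_full_mass(cp: CompoundPeptidoform, q: int, model: FragmentationModel) -> List[_Mass]:
    """Full-chain mass variants of peptidoform q (H2O, all located/terminal mods)."""
    ctx = _PeptidoformContext(cp, q, model)
    variants = ctx.stretch_masses(0, len(ctx.pep))
    out = []
    for v in variants:
        m = v.add(WATER).add(ctx.n_term_mass.formula, ctx.n_term_mass.extra)
        m = m.add(ctx.c_term_mass.formula, ctx.c_term_mass.extra)
        for df, de, tag in ctx.unknown_mods:
            m = m.add(df, de, None)  # unknown-position mods always count in full chains
        out.append(m)
    return out


def _crosslink_choices(
    cp: CompoundPeptidoform,
    model: FragmentationModel,
    p_idx: int,
    residue_range: Tuple[int, int],
) -> Optional[List[_Mass]]:
    """Cross-link mass contributions for a backbone stretch.

    Returns a list of alternative contributions (possibly just the empty
    one), or None when the position lies in a cyclic region with no way to
    break out (no fragment at all).
    """
    lo, hi = residue_range
    in_stretch = lambda p, r: p == p_idx and lo <= r < hi

    internal: List[CrossLink] = []
    spanning: List[Tuple[CrossLink, Tuple[int, int]]] = []  # (link, outside endpoint)
    for link in cp.crosslinks.values():
        inside = [s for s in link.sites if in_stretch(*s)]
        if len(inside) == 2:
            internal.append(link)
        elif len(inside) == 1:
            outside = link.sites[0] if link.sites[1] == inside[0] else link.sites[1]
            spanning.append((link, outside))

    base = _Mass()
    for link in internal:
        df = link.definition.formula if link.definition.formula is not None else _EMPTY
        base = base.add(df, 0.0 if link.definition.formula is not None
                        else link.definition.mass)
    if not spanning:
        return [base]

    choices: List[_Mass] = []
    option_sets = []
    for link, _ in spanning:
        opts = [("intact", None)] + [("break", rule) for rule in link.definition.breakage_rules]
        option_sets.append(opts)
    for assignment in itertools.product(*option_sets):
        intact_links = [spanning[i][0] for i, (mode, _) in enumerate(assignment)
                        if mode == "intact"]
        # walk the complex attached through intact links
        reached_peps: Set[int] = set()
        queue = [outside for (link, outside), (mode, _) in zip(spanning, assignment)
                 if mode == "intact"]
        cyclic = False
        while queue:
            q_pep, _q_res = queue.pop()
            if q_pep == p_idx:
                cyclic = True  # path leads back to the cut chain: cyclic region
                break
            if q_pep in reached_peps:
                continue
            reached_peps.add(q_pep)
            for other in cp.crosslinks.values():
                if other in [s[0] for s in spanning]:
                    continue
                ends = list(other.sites)
                touching = [e for e in ends if e[0] == q_pep]
                if touching:
                    for e in ends:
                        if e[0] != q_pep:
                            queue.append(e)
        if cyclic:
            continue
        m = base
        for (link, _), (mode, rule) in zip(spanning, assignment):
            if mode == "intact":
                df = link.definition.formula if link.definition.formula is not None else _EMPTY
                m = m.add(df, 0.0 if link.definition.formula is not None
                          else link.definition.mass, f"xl:{link.name}")
            else:
                m = m.add(rule.retained, 0.0, f"xl:{link.name}:{rule.label()}")
        for q in sorted(reached_peps):
            partner_variants = _chain_full_mass(cp, q, model)
            m = m.add(partner_variants[0].formula, partner_variants[0].extra)
            # internal links of the partner chains
        for other in cp.crosslinks.values():
            if all(s[0] in reached_peps for s in other.sites):
                df = other.definition.formula if other.definition.formula is not None else _EMPTY
                m = m.add(df)
        choices.append(m)
    if not choices:
        return None
    return choices


# -- loss combinations ---------------------------------------------------------


def _loss_combinations(
    pool: Sequence[ElementalFormula], max_losses: int
) -> List[Tuple[ElementalFormula, Tuple[str, ...]]]:
    """The no-loss case plus every distinct loss combo up to ``max_losses``."""
    out: List[Tuple[ElementalFormula, Tuple[str, ...]]] = [(_EMPTY, ())]
    seen = {(): None}
    distinct = list(dict.fromkeys(pool))
    for count in range(1, max_losses + 1):
        for combo in itertools.combinations(distinct, count):
            key = tuple(sorted(f.text() for f in combo))
            if key in seen:
                continue
            seen[key] = None
            total = _EMPTY
            for f in combo:
                total = total + f
            out.append((total, tuple(f"-{f.text()}" for f in combo)))
    return out


# -- fragment emission ---------------------------------------------------------


def _emit(
    frags: Dict[tuple, TheoreticalFragment],
    kind: str,
    p_idx: int,
    position: Optional[int],
    base: _Mass,
    delta: ElementalFormula,
    h_offset: int,
    losses: Tuple[ElementalFormula, Tuple[str, ...]],
    charge: int,
    isotopes: Mapping[str, int],
    label_core: str,
    extra_tag: str = "",
) -> None:
    loss_formula, loss_tags = losses
    formula = base.formula + delta + (HYDROGEN * h_offset) - loss_formula
    neutral = formula.with_isotope_substitution(isotopes).mass + base.extra
    if neutral <= 0:
        return
    variant_bits = list(base.tags)
    if h_offset:
        variant_bits.append(f"{h_offset:+d}H")
    if extra_tag:
        variant_bits.append(extra_tag)
    variant = ",".join(variant_bits)
    label = label_core
    if h_offset:
        label += "." if h_offset == 1 else f"{h_offset:+d}H"
    label += "".join(loss_tags)
    if charge != 1:
        label += f"^{charge}+"
    frag = TheoreticalFragment(
        kind=kind,
        peptidoform_index=p_idx,
        position=position,
        charge=charge,
        neutral_mass=neutral,
        formula=formula if base.extra == 0 else None,
        losses=loss_tags,
        variant=variant,
        label=label,
    )
    key = frag.identity() + (round(neutral, 6),)
    frags.setdefault(key, frag)


def _with_unknown_mods(ctx: _PeptidoformContext, variants: List[_Mass]) -> List[_Mass]:
    """Expand with optional unknown-position mod placements (as variants)."""
    out = list(variants)
    for df, de, tag in ctx.unknown_mods:
        out.extend(v.add(df, de, tag) for v in list(out))
    return _cap(out)


def _backbone_for_pep(
    cp: CompoundPeptidoform,
    p_idx: int,
    model: FragmentationModel,
    precursor_charge: Optional[int],
    frags: Dict[tuple, TheoreticalFragment],
) -> None:
    ctx = _PeptidoformContext(cp, p_idx, model)
    pep = ctx.pep
    n = len(pep)
    iso = pep.isotopes
    n_series = [k for k in ("a", "b", "c") if model.series_settings(k).enabled]
    c_series = [k for k in ("x", "y", "z") if model.series_settings(k).enabled]
    sat_d = model.series_settings("d").enabled
    sat_v = model.series_settings("v").enabled
    sat_w = model.series_settings("w").enabled

    prefix_variants = [_Mass().add(ctx.n_term_mass.formula, ctx.n_term_mass.extra)]
    for i in range(1, n):
        prefix_variants = _cap([
            v.add(alt.formula, alt.extra) if not alt.tags
            else replace(v.add(alt.formula, alt.extra), tags=v.tags + alt.tags)
            for v in prefix_variants for alt in ctx.residue_masses[i - 1]
        ])
        if n_series or sat_d:
            xl = _crosslink_choices(cp, model, p_idx, (0, i))
            if xl is None:
                continue  # cyclic region: no N-terminal fragments at this position
            mod_losses = ctx.stretch_losses(0, i)
            bases = _with_unknown_mods(
                ctx, _cap([pv.add(x.formula, x.extra) if not x.tags
                           else replace(pv.add(x.formula, x.extra), tags=pv.tags + x.tags)
                           for pv in prefix_variants for x in xl])
            )
            for kind in n_series:
                settings = model.series_settings(kind)
                combos = _loss_combinations(tuple(settings.losses) + tuple(mod_losses),
                                            settings.max_losses)
                for base in bases:
                    for h in settings.h_variants:
                        for losses in combos:
                            for charge in settings.charge_list(precursor_charge):
                                _emit(frags, kind, p_idx, i, base, _BACKBONE_DELTA[kind],
                                      h, losses, charge, iso, f"{kind}{i}")
            if sat_d:
                settings = model.series_settings("d")
                combos = _loss_combinations(tuple(settings.losses) + tuple(mod_losses),
                                            settings.max_losses)
                for distal_text in model.distal_groups.get(pep.sequence[i - 1], ()):
                    distal = parse_formula(distal_text)
                    delta = _BACKBONE_DELTA["a"] + HYDROGEN - distal
                    for base in bases:
                        for losses in combos:
                            for charge in settings.charge_list(precursor_charge):
                                _emit(frags, "d", p_idx, i, base, delta, 0, losses,
                                      charge, iso, f"d{i}", extra_tag=f"distal:{distal_text}")

    suffix_variants = [_Mass(WATER).add(ctx.c_term_mass.formula, ctx.c_term_mass.extra)]
    for j in range(1, n):
        res = n - j  # 0-based index of the residue just added to the suffix
        suffix_variants = _cap([
            v.add(alt.formula, alt.extra) if not alt.tags
            else replace(v.add(alt.formula, alt.extra), tags=v.tags + alt.tags)
            for v in suffix_variants for alt in ctx.residue_masses[res]
        ])
        if not (c_series or sat_v or sat_w):
            continue
        xl = _crosslink_choices(cp, model, p_idx, (res, n))
        if xl is None:
            continue
        mod_losses = ctx.stretch_losses(res, n)
        bases = _with_unknown_mods(
            ctx, _cap([sv.add(x.formula, x.extra) if not x.tags
                       else replace(sv.add(x.formula, x.extra), tags=sv.tags + x.tags)
                       for sv in suffix_variants for x in xl])
        )
        for kind in c_series:
            settings = model.series_settings(kind)
            combos = _loss_combinations(tuple(settings.losses) + tuple(mod_losses),
                                        settings.max_losses)
            for base in bases:
                for h in settings.h_variants:
                    for losses in combos:
                        for charge in settings.charge_list(precursor_charge):
                            _emit(frags, kind, p_idx, j, base, _BACKBONE_DELTA[kind],
                                  h, losses, charge, iso, f"{kind}{j}")
        terminal_res = pep.sequence[res]
        if sat_w:
            settings = model.series_settings("w")
            combos = _loss_combinations(settings.losses, settings.max_losses)
            for distal_text in model.distal_groups.get(terminal_res, ()):
                distal = parse_formula(distal_text)
                # w = z-dot - distal radical
                delta = _BACKBONE_DELTA["z"] + HYDROGEN - distal
                for base in bases:
                    for losses in combos:
                        for charge in settings.charge_list(precursor_charge):
                            _emit(frags, "w", p_idx, j, base, delta, 0, losses,
                                  charge, iso, f"w{j}", extra_tag=f"distal:{distal_text}")
        if sat_v and terminal_res not in _NO_V_IONS:
            settings = model.series_settings("v")
            combos = _loss_combinations(settings.losses, settings.max_losses)
            from .chem import AMINO_ACIDS as _AA
            if terminal_res in _AA:
                sidechain = _AA[terminal_res] - _RESIDUE_BACKBONE
                delta = HYDROGEN - sidechain
                for base in bases:
                    for losses in combos:
                        for charge in settings.charge_list(precursor_charge):
                            _emit(frags, "v", p_idx, j, base, delta, 0, losses,
                                  charge, iso, f"v{j}")


def backbone_fragments(
    cp: CompoundPeptidoform,
    model: FragmentationModel,
    precursor_charge: Optional[int] = None,
) -> List[TheoreticalFragment]:
    """All enabled a/b/c/x/y/z fragments for every member peptidoform."""
    only_backbone = replace(
        model,
        series={k: s for k, s in model.series.items() if k in BACKBONE_SERIES},
    )
    frags: Dict[tuple, TheoreticalFragment] = {}
    for p_idx in range(len(cp.peptidoforms)):
        _backbone_for_pep(cp, p_idx, only_backbone, precursor_charge, frags)
    return sorted(frags.values(), key=lambda f: f.mz)


def satellite_fragments(
    cp: CompoundPeptidoform,
    model: FragmentationModel,
    precursor_charge: Optional[int] = None,
) -> List[TheoreticalFragment]:
    """All enabled d/v/w satellite fragments."""
    only_sat = replace(
        model,
        series={k: s for k, s in model.series.items() if k in SATELLITE_SERIES},
    )
    frags: Dict[tuple, TheoreticalFragment] = {}
    for p_idx in range(len(cp.peptidoforms)):
        _backbone_for_pep(cp, p_idx, only_sat, precursor_charge, frags)
    return sorted(frags.values(), key=lambda f: f.mz)


def immonium_fragments(cp: CompoundPeptidoform) -> List[TheoreticalFragment]:
    """Immonium ions (1+), one per distinct residue/located-mod combination."""
    frags: Dict[tuple, TheoreticalFragment] = {}
    for p_idx, pep in enumerate(cp.peptidoforms):
        for i in range(len(pep)):
            has_xl = any(isinstance(a, CrossLinkAttachment) for a in pep.residue_mods[i])
            if has_xl:
                continue
            for formula, tag_aa in pep.residue_alternatives(i):
                m = _Mass(formula)
                mod_names = []
                for att in pep.residue_mods[i]:
                    df, de, _ = _attachment_contribution(att, pep.sequence[i])
                    m = m.add(df, de)
                    mod_names.append(_attachment_name(att))
                formula_imm = m.formula - CARBON_MONOXIDE
                neutral = formula_imm.with_isotope_substitution(pep.isotopes).mass + m.extra
                if neutral <= 0:
                    continue
                label = f"imm:{tag_aa}" + ("".join(f"[{n}]" for n in mod_names))
                key = ("immonium", p_idx, label)
                frags.setdefault(key, TheoreticalFragment(
                    kind="immonium", peptidoform_index=p_idx, position=None, charge=1,
                    neutral_mass=neutral, formula=formula_imm if m.extra == 0 else None,
                    variant=label, label=label,
                ))
    return sorted(frags.values(), key=lambda f: f.mz)


def _complexes(cp: CompoundPeptidoform) -> List[List[int]]:
    """Group member peptidoforms into cross-linked complexes (chimeras stay apart)."""
    parent = list(range(len(cp.peptidoforms)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for link in cp.crosslinks.values():
        a, b = link.sites[0][0], link.sites[1][0]
        parent[find(a)] = find(b)
    groups: Dict[int, List[int]] = {}
    for i in range(len(cp.peptidoforms)):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def precursor_fragments(
    cp: CompoundPeptidoform,
    model: FragmentationModel,
    precursor_charge: Optional[int] = None,
) -> List[TheoreticalFragment]:
    """Intact species per chimeric member / cross-linked complex, with losses.

    The charge list defaults to 1..precursor charge, which covers matching
    of decharged (deconvoluted) precursor fragments.
    """
    frags: Dict[tuple, TheoreticalFragment] = {}
    for group in _complexes(cp):
        rep = group[0]
        variants = [_Mass()]
        loss_pool: List[ElementalFormula] = list(model.precursor_losses)
        iso = cp.peptidoforms[rep].isotopes
        for q in group:
            pep = cp.peptidoforms[q]
            chain = _chain_full_mass(cp, q, model)
            variants = _cap([v.add(c.formula, c.extra) if not c.tags
                             else replace(v.add(c.formula, c.extra), tags=v.tags + c.tags)
                             for v in variants for c in chain])
            for att in pep.labile:
                df, de, _ = _attachment_contribution(att, None)
                variants = [v.add(df, de) for v in variants]
            for i, mods in enumerate(pep.residue_mods):
                for att in mods:
                    if isinstance(att, ModAttachment) and not isinstance(
                        att.definition, BareMassModification
                    ):
                        loss_pool.extend(att.definition.losses_for_residue(pep.sequence[i]))
                loss_pool.extend(model.sidechain_losses.get(pep.sequence[i], ()))
        for link in cp.crosslinks.values():
            if link.sites[0][0] in group:
                df = link.definition.formula
                variants = [v.add(df if df is not None else _EMPTY,
                                  0.0 if df is not None else link.definition.mass)
                            for v in variants]
        if precursor_charge is None:
            member_charge = cp.peptidoforms[rep].charge
            top = member_charge or 1
        else:
            top = precursor_charge
        charges = (list(model.precursor_charges) if model.precursor_charges
                   else list(range(1, top + 1)))
        combos = _loss_combinations(loss_pool, model.precursor_max_losses)
        for base in variants:
            for losses in combos:
                for charge in charges:
                    _emit(frags, "precursor", rep, None, base, _EMPTY, 0, losses,
                          charge, iso, "M")
    return sorted(frags.values(), key=lambda f: f.mz)


def _glycan_and_diagnostic_fragments(
    cp: CompoundPeptidoform,
    model: FragmentationModel,
    precursor_charge: Optional[int],
) -> List[TheoreticalFragment]:
    frags: Dict[tuple, TheoreticalFragment] = {}
    for p_idx, pep in enumerate(cp.peptidoforms):
        iso = pep.isotopes
        located = [(i, att) for i, mods in enumerate(pep.residue_mods) for att in mods]
        terminal = [(None, att) for att in pep.n_term + pep.c_term + pep.labile
                    + pep.unknown_position]
        # modification diagnostic ions, singly protonated
        if model.diagnostic_ions:
            for _, att in located + terminal:
                if isinstance(att, ModAttachment) and not isinstance(
                    att.definition, BareMassModification
                ):
                    for k, dia in enumerate(att.definition.diagnostic_ions):
                        neutral = dia.with_isotope_substitution(iso).mass
                        label = f"diag:{att.definition.name}:{k}"
                        key = ("diagnostic", p_idx, label)
                        frags.setdefault(key, TheoreticalFragment(
                            kind="diagnostic", peptidoform_index=p_idx, position=None,
                            charge=1, neutral_mass=neutral, formula=dia,
                            variant=label, label=label,
                        ))
        if not model.glycan_enabled:
            continue
        glycans = [(i, att) for i, att in located + terminal
                   if isinstance(att, GlycanAttachment)]
        if not glycans:
            continue
        peptide_wo = _peptide_mass_without_glycans(cp, p_idx, model)
        for site, att in glycans:
            labile = att in pep.labile
            if att.tree is not None:
                pieces = topology_fragments(att.tree, model.glycan_max_breaks)
                b_pieces = [g for g in pieces if g.kind == "B"]
                y_pieces = [g for g in pieces if g.kind == "Y"]
            else:
                b_pieces, y_pieces = composition_fragments(
                    att.composition, model.glycan_min_size,
                    model.glycan_max_size or att.composition.size,
                )
            for g in b_pieces:
                if g.composition.size == 0:
                    continue
                for charge in model.glycan_b_charges:
                    neutral = g.glycan_formula.with_isotope_substitution(iso).mass
                    label = g.label() + (f"^{charge}+" if charge != 1 else "")
                    key = ("glycan_B", p_idx, label)
                    frags.setdefault(key, TheoreticalFragment(
                        kind="glycan_B", peptidoform_index=p_idx, position=None,
                        charge=charge, neutral_mass=neutral, formula=g.glycan_formula,
                        variant=g.label(), label=label,
                    ))
            top = precursor_charge or pep.charge or 1
            for g in y_pieces:
                base = peptide_wo.add(g.glycan_formula)
                neutral = base.formula.with_isotope_substitution(iso).mass + base.extra
                for charge in range(1, top + 1):
                    label = g.label() + (f"^{charge}+" if charge != 1 else "")
                    key = ("glycan_Y", p_idx, label, round(neutral, 6))
                    frags.setdefault(key, TheoreticalFragment(
                        kind="glycan_Y", peptidoform_index=p_idx, position=None,
                        charge=charge, neutral_mass=neutral,
                        formula=base.formula if base.extra == 0 else None,
                        variant=g.label(), label=label,
                    ))
            # oxonium diagnostics for the involved monosaccharide kinds
            if model.diagnostic_ions:
                for label, ion_mz in glycan_diagnostic_ions(
                    [k for k, _ in att.composition.counts]
                ):
                    key = ("diagnostic", p_idx, label)
                    frags.setdefault(key, TheoreticalFragment(
                        kind="diagnostic", peptidoform_index=p_idx, position=None,
                        charge=1, neutral_mass=ion_mz - PROTON_MASS, formula=None,
                        variant=label, label=label,
                    ))
    return list(frags.values())


def _peptide_mass_without_glycans(
    cp: CompoundPeptidoform, p_idx: int, model: FragmentationModel
) -> _Mass:
    """Full-chain mass of one member with every glycan attachment removed."""
    pep = cp.peptidoforms[p_idx]
    m = _Mass(WATER)
    for i in range(len(pep)):
        formula, _ = pep.residue_alternatives(i)[0]
        m = m.add(formula)
        for att in pep.residue_mods[i]:
            if isinstance(att, (GlycanAttachment, CrossLinkAttachment)):
                continue
            df, de, _ = _attachment_contribution(att, pep.sequence[i])
            m = m.add(df, de)
    for att in pep.n_term + pep.c_term + pep.unknown_position:
        if isinstance(att, (GlycanAttachment, CrossLinkAttachment)):
            continue
        df, de, _ = _attachment_contribution(att, None)
        m = m.add(df, de)
    return m


def generate_fragments(
    cp: CompoundPeptidoform,
    model: FragmentationModel,
    precursor_charge: Optional[int] = None,
) -> List[TheoreticalFragment]:
    """The union of all fragment kinds the model enables, deduplicated.

    Deduplication key: (kind, peptidoform, position, variant, losses,
    charge, rounded mass).
    """
    if precursor_charge is None:
        precursor_charge = cp.precursor_charge
    out: Dict[tuple, TheoreticalFragment] = {}
    for frag in itertools.chain(
        backbone_fragments(cp, model, precursor_charge),
        satellite_fragments(cp, model, precursor_charge),
        immonium_fragments(cp) if model.immonium else (),
        precursor_fragments(cp, model, precursor_charge),
        _glycan_and_diagnostic_fragments(cp, model, precursor_charge),
    ):
        out.setdefault(frag.identity() + (round(frag.neutral_mass, 6),), frag)
    return sorted(out.values(), key=lambda f: f.mz)
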
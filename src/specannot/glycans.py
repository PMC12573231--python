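"""Glycan models and glycosidic fragment enumeration.

Glycans are handled in two forms, mirroring the two ProForma notations:

* a *composition* (``[Glycan:HexNAc3Hex4]``) — an unordered multiset of
  monosaccharides; fragments are all distinct sub-multisets;
* a *topology* — a rooted tree of monosaccharides; fragments are all
  connected subgraphs, annotated with the glycosidic bonds broken.

Fragment chemistry: glycosidic cleavage transfers no hydrogen, so a B ion
is the plain sum of its residue formulas (the oxocarbenium arises on
protonation, giving the canonical HexNAc oxonium at m/z 204.0867) and a Y
ion is the peptide plus the retained residues.  Internal/oxonium ions are
simply B fragments with more than one broken bond; no separate kind is
needed.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .chem import (
    DEFAULT_OXONIUM_LOSSES,
    MONOSACCHARIDES,
    ElementalFormula,
    PROTON_MASS,
    parse_formula,
)

__all__ = [
    "GlycanComposition",
    "GlycanTree",
    "GlycanFragment",
    "GlycanParseError",
    "parse_glycan_composition",
    "parse_glycan_topology",
    "composition_fragments",
    "topology_fragments",
    "glycan_diagnostic_ions",
    "load_glycan_structures",
]

_EMPTY = ElementalFormula()


class GlycanParseError(ValueError):
    """Malformed glycan composition or topology text."""


@dataclass(frozen=True)
class GlycanComposition:
    """Multiset of monosaccharide kinds."""

    counts: Tuple[Tuple[str, int], ...]  # sorted (kind, count>=1) pairs

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "GlycanComposition":
        items = tuple(sorted((k, int(n)) for k, n in mapping.items() if n))
        for kind, n in items:
            if n < 1:
                raise GlycanParseError(f"negative count for {kind}")
        return cls(items)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    @property
    def size(self) -> int:
        return sum(n for _, n in self.counts)

    def formula(self, table: Mapping[str, ElementalFormula] = MONOSACCHARIDES) -> ElementalFormula:
        total = _EMPTY
        for kind, n in self.counts:
            if kind not in table:
                raise GlycanParseError(f"unknown monosaccharide {kind!r}")
            total = total + table[kind] * n
        return total

    def text(self) -> str:
        return "".join(f"{k}{n}" for k, n in self.counts)

    def __str__(self) -> str:
        return self.text()


_COMPOSITION_TOKEN = re.compile(r"([A-Za-z]+?)(\d+)|([A-Za-z]+)")


def parse_glycan_composition(
    text: str, table: Mapping[str, ElementalFormula] = MONOSACCHARIDES
) -> GlycanComposition:
    """Parse ``"HexNAc3Hex4"``-style composition text (count defaults to 1)."""
    counts: Dict[str, int] = {}
    pos = 0
    text = text.strip()
    # longest-match against the known kinds to avoid "Hex" swallowing "HexNAc"
    kinds = sorted(table, key=len, reverse=True)
    while pos < len(text):
        for kind in kinds:
            if text.startswith(kind, pos):
                pos += len(kind)
                m = re.match(r"\d+", text[pos:])
                n = int(m.group()) if m else 1
                pos += m.end() if m else 0
                counts[kind] = counts.get(kind, 0) + n
                break
        else:
            raise GlycanParseError(f"unknown monosaccharide at {text[pos:]!r}")
    if not counts:
        raise GlycanParseError("empty glycan composition")
    return GlycanComposition.from_mapping(counts)


@dataclass(frozen=True)
class GlycanTree:
    """Rooted glycan topology.

    Nodes are stored in depth-first preorder; ``parents[i]`` is the parent
    index of node ``i`` (-1 for the root).  Edge ``i`` (i >= 1) is the bond
    from node ``i`` to its parent; edge 0 is the root attachment to the
    peptide.
    """

    kinds: Tuple[str, ...]
    parents: Tuple[int, ...]

    def __post_init__(self):
        if not self.kinds or self.parents[0] != -1:
            raise GlycanParseError("tree must have a root node first")

    @property
    def n_nodes(self) -> int:
        return len(self.kinds)

    def composition(self) -> GlycanComposition:
        counts: Dict[str, int] = {}
        for k in self.kinds:
            counts[k] = counts.get(k, 0) + 1
        return GlycanComposition.from_mapping(counts)

    def formula(self, table: Mapping[str, ElementalFormula] = MONOSACCHARIDES) -> ElementalFormula:
        return self.composition().formula(table)

    def children(self, i: int) -> List[int]:
        return [j for j, p in enumerate(self.parents) if p == i]

    def text(self) -> str:
        def render(i: int) -> str:
            kids = self.children(i)
            if not kids:
                return self.kinds[i]
            return self.kinds[i] + "(" + ",".join(render(k) for k in kids) + ")"

        return render(0)


def parse_glycan_topology(
    text: str, table: Mapping[str, ElementalFormula] = MONOSACCHARIDES
) -> GlycanTree:
    """Parse the topology mini-grammar ``KIND ["(" tree {"," tree} ")"]``.

    The root is written first; e.g. ``"HexNAc(HexNAc(Hex(Hex,Hex)))"``.
    """
    kinds: List[str] = []
    parents: List[int] = []
    kinds_sorted = sorted(table, key=len, reverse=True)
    pos = 0
    text = text.strip()

    def parse_node(parent: int) -> None:
        nonlocal pos
        for kind in kinds_sorted:
            if text.startswith(kind, pos):
                pos += len(kind)
                break
        else:
            raise GlycanParseError(f"unknown monosaccharide at {text[pos:]!r}")
        idx = len(kinds)
        kinds.append(kind)
        parents.append(parent)
        if pos < len(text) and text[pos] == "(":
            pos += 1
            parse_node(idx)
            while pos < len(text) and text[pos] == ",":
                pos += 1
                parse_node(idx)
            if pos >= len(text) or text[pos] != ")":
                raise GlycanParseError(f"unbalanced parentheses in {text!r}")
            pos += 1

    parse_node(-1)
    if pos != len(text):
        raise GlycanParseError(f"trailing characters {text[pos:]!r} in {text!r}")
    return GlycanTree(tuple(kinds), tuple(parents))


@dataclass(frozen=True)
class GlycanFragment:
    """One glycosidic fragment: a B piece or a Y (peptide-retaining) piece."""

    kind: str  # "B" | "Y"
    #: retained monosaccharide composition (empty for Y0)
    composition: GlycanComposition
    #: broken bond indices (topology mode) or None (composition mode)
    broken_bonds: Optional[Tuple[int, ...]]
    #: neutral formula of the glycan part (Y: add the peptide separately)
    glycan_formula: ElementalFormula

    @property
    def n_breaks(self) -> int:
        return len(self.broken_bonds) if self.broken_bonds is not None else 1

    def label(self) -> str:
        comp = self.composition.text() or "0"
        if self.broken_bonds:
            return f"{self.kind}({comp})b{{{','.join(map(str, self.broken_bonds))}}}"
        return f"{self.kind}({comp})"


def composition_fragments(
    composition: GlycanComposition,
    min_size: int = 1,
    max_size: Optional[int] = None,
    table: Mapping[str, ElementalFormula] = MONOSACCHARIDES,
) -> Tuple[List[GlycanFragment], List[GlycanFragment]]:
    """All B and Y candidates of a composition glycan.

    B candidates are every distinct non-empty sub-multiset with size within
    ``[min_size, max_size]``; Y candidates retain every distinct sub-multiset
    of size <= ``max_size`` — plus always the empty set (Y0) and the full
    composition (intact).  Returns ``(b_fragments, y_fragments)``.
    """
    if max_size is None:
        max_size = composition.size
    if min_size < 1 or min_size > max_size:
        raise ValueError(f"invalid size bounds [{min_size}, {max_size}]")
    kinds = [k for k, _ in composition.counts]
    ranges = [range(n + 1) for _, n in composition.counts]
    b_frags: List[GlycanFragment] = []
    y_frags: List[GlycanFragment] = []
    for combo in itertools.product(*ranges):
        sub = {k: c for k, c in zip(kinds, combo) if c}
        size = sum(combo)
        subcomp = GlycanComposition.from_mapping(sub)
        formula = subcomp.formula(table)
        if min_size <= size <= max_size:
            b_frags.append(GlycanFragment("B", subcomp, None, formula))
        if size <= max_size or size == composition.size:
            y_frags.append(GlycanFragment("Y", subcomp, None, formula))
    return b_frags, y_frags


def _connected_subsets(tree: GlycanTree) -> List[FrozenSet[int]]:
    """All node subsets inducing a connected subgraph (brute force)."""
    n = tree.n_nodes
    subsets: List[FrozenSet[int]] = []
    for mask in range(1, 1 << n):
        nodes = frozenset(i for i in range(n) if mask >> i & 1)
        # connected in a rooted tree <=> exactly one node's parent is outside
        tops = [i for i in nodes if tree.parents[i] not in nodes]
        if len(tops) == 1:
            subsets.append(nodes)
    return subsets


def topology_fragments(
    tree: GlycanTree,
    max_breaks: Optional[int] = None,
    peptide_formula: ElementalFormula = _EMPTY,
    table: Mapping[str, ElementalFormula] = MONOSACCHARIDES,
) -> List[GlycanFragment]:
    """All glycosidic fragments of a topology glycan.

    Every connected subgraph yields one fragment: root-containing subsets
    become Y ions (peptide + retained nodes), the rest become B ions.  The
    empty retained set is Y0 (bare peptide, root bond broken).  Broken bonds
    are the edges from the retained set to removed neighbours, plus the root
    attachment for B ions.  Fragments with more than ``max_breaks`` broken
    bonds are dropped (the intact glycopeptide has zero breaks).
    """
    frags: List[GlycanFragment] = []

    def make(kind: str, nodes: FrozenSet[int], broken: Tuple[int, ...]) -> GlycanFragment:
        counts: Dict[str, int] = {}
        formula = _EMPTY
        for i in nodes:
            counts[tree.kinds[i]] = counts.get(tree.kinds[i], 0) + 1
            formula = formula + table[tree.kinds[i]]
        if kind == "Y":
            formula = formula + peptide_formula
        return GlycanFragment(kind, GlycanComposition.from_mapping(counts), broken, formula)

    # Y0 and its complement: bare peptide, and the intact glycan detached at
    # the root attachment (the full-glycan oxonium, e.g. 204.0867 for a
    # single HexNAc)
    frags.append(make("Y", frozenset(), (0,)))
    frags.append(make("B", frozenset(range(tree.n_nodes)), (0,)))
    for nodes in _connected_subsets(tree):
        cut_children = tuple(
            sorted(j for j in range(tree.n_nodes) if j not in nodes and tree.parents[j] in nodes)
        )
        if 0 in nodes:
            broken = cut_children
            kind = "Y"
        else:
            top = next(i for i in nodes if tree.parents[i] not in nodes)
            broken = tuple(sorted((top,) + cut_children))
            kind = "B"
        frags.append(make(kind, nodes, broken))
    if max_breaks is not None:
        frags = [f for f in frags if f.n_breaks <= max_breaks or not f.broken_bonds]
    return frags


def glycan_diagnostic_ions(
    kinds: Sequence[str],
    table: Mapping[str, ElementalFormula] = MONOSACCHARIDES,
    losses: Mapping[str, Sequence[str]] = DEFAULT_OXONIUM_LOSSES,
) -> List[Tuple[str, float]]:
    """Oxonium-type diagnostic ions (1+) for a set of monosaccharide kinds.

    Per kind: the base oxonium (residue + proton) plus the configured
    secondary losses.  Returns ``(label, m/z)`` pairs.
    """
    out: List[Tuple[str, float]] = []
    for kind in sorted(set(kinds)):
        if kind not in table:
            raise GlycanParseError(f"unknown monosaccharide {kind!r}")
        base = table[kind].mass
        out.append((f"oxonium:{kind}", base + PROTON_MASS))
        for loss_text in losses.get(kind, ()):
            loss = parse_formula(loss_text)
            out.append((f"oxonium:{kind}-{loss_text}", base - loss.mass + PROTON_MASS))
    return out


def load_glycan_structures(path) -> Dict[str, GlycanTree]:
    """Load a TSV of ``id<TAB>topology`` rows (a local GNOme stand-in)."""
    structures: Dict[str, GlycanTree] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GlycanParseError(f"{path}:{line_no}: expected 'id<TAB>topology'")
            structures[parts[0]] = parse_glycan_topology(parts[1])
    return structures
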
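import itertools
import math
import random

import networkx as nx
import pytest

from specannot.chem import AMINO_ACIDS, MONOSACCHARIDES, WATER
from specannot.glycans import (
    GlycanParseError,
    GlycanTree,
    composition_fragments,
    glycan_diagnostic_ions,
    parse_glycan_composition,
    parse_glycan_topology,
    topology_fragments,
)


class TestTopologyParsing:
    def test_single_node(self):
        t = parse_glycan_topology("HexNAc")
        assert t.n_nodes == 1 and t.parents == (-1,)

    def test_linear_then_branching(self):
        t = parse_glycan_topology("HexNAc(HexNAc(Hex(Hex,Hex)))")
        assert t.kinds == ("HexNAc", "HexNAc", "Hex", "Hex", "Hex")
        assert t.parents == (-1, 0, 1, 2, 2)

    def test_round_trip(self):
        text = "HexNAc(HexNAc(Hex(Hex(HexNAc),Hex(HexNAc,dHex))))"
        assert parse_glycan_topology(text).text() == text

    @pytest.mark.parametrize("bad", ["Hex(", "Hex)", "Foo", "Hex(Hex", "Hex(Hex))"])
    def test_errors(self, bad):
        with pytest.raises(GlycanParseError):
            parse_glycan_topology(bad)


class TestCompositionFragments:
    def test_count_matches_closed_form(self):
        comp = parse_glycan_composition("HexNAc3Hex4")
        b, _ = composition_fragments(comp)
        assert len([f for f in b if f.composition.size > 0]) == (3 + 1) * (4 + 1) - 1 == 19

    def test_hexnac_oxonium(self):
        comp = parse_glycan_composition("HexNAc1")
        b, _ = composition_fragments(comp)
        (frag,) = [f for f in b if f.composition.size]
        from specannot.chem import PROTON_MASS
        assert frag.glycan_formula.mass + PROTON_MASS == pytest.approx(204.086650, abs=1e-5)

    def test_bounds_filter(self):
        comp = parse_glycan_composition("HexNAc1Hex1")
        b, _ = composition_fragments(comp, 2, 2)
        assert len(b) == 1 and b[0].composition.as_dict() == {"HexNAc": 1, "Hex": 1}

    def test_y_includes_empty_and_full(self):
        comp = parse_glycan_composition("HexNAc2Hex1")
        _, y = composition_fragments(comp, 1, 1)
        sizes = sorted(f.composition.size for f in y)
        assert sizes[0] == 0 and sizes[-1] == comp.size

    @pytest.mark.parametrize("text", ["Hex2HexNAc2", "NeuAc1Hex3", "dHex1HexNAc4Pen2"])
    def test_unbounded_count_closed_form(self, text):
        comp = parse_glycan_composition(text)
        b, _ = composition_fragments(comp)
        expected = math.prod(n + 1 for _, n in comp.counts) - 1
        assert len([f for f in b if f.composition.size > 0]) == expected

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            composition_fragments(parse_glycan_composition("Hex1"), 2, 1)


def _oracle_fragments(tree: GlycanTree):
    """Brute-force oracle: classify every connected node subset with networkx."""
    g = nx.Graph()
    g.add_nodes_from(range(tree.n_nodes))
    for i in range(1, tree.n_nodes):
        g.add_edge(i, tree.parents[i])
    out = set()
    out.add(("Y", frozenset(), frozenset([0])))  # Y0: root bond broken
    out.add(("B", frozenset(range(tree.n_nodes)), frozenset([0])))  # full glycan
    for r in range(1, tree.n_nodes + 1):
        for nodes in itertools.combinations(range(tree.n_nodes), r):
            nodes = frozenset(nodes)
            if not nx.is_connected(g.subgraph(nodes)):
                continue
            cuts = {j for j in range(tree.n_nodes)
                    if (j in nodes) != (tree.parents[j] in nodes) and tree.parents[j] != -1}
            if 0 in nodes:
                out.add(("Y", nodes, frozenset(cuts)))
            else:
                top = min(j for j in nodes if tree.parents[j] not in nodes)
                out.add(("B", nodes, frozenset(cuts | {top})))
    return out


def _random_tree(rng: random.Random, n: int) -> GlycanTree:
    kinds = tuple(rng.choice(list(MONOSACCHARIDES)) for _ in range(n))
    parents = (-1,) + tuple(rng.randint(0, i - 1) for i in range(1, n))
    return GlycanTree(kinds, parents)


class TestTopologyFragments:
    def test_chain_of_three(self):
        t = parse_glycan_topology("Hex(Hex(Hex))")
        frags = topology_fragments(t)
        y = [f for f in frags if f.kind == "Y"]
        b = [f for f in frags if f.kind == "B"]
        assert len(y) == 4  # retain 0, 1, 2, 3 nodes
        assert len(b) == 4  # {A}, {A,B}, {B}, and the full glycan detached

    def test_star(self):
        t = parse_glycan_topology("Hex(HexNAc,NeuAc)")
        frags = topology_fragments(t)
        assert len([f for f in frags if f.kind == "Y"]) == 5
        assert len([f for f in frags if f.kind == "B"]) == 3  # {x}, {y}, full

    def test_single_node(self):
        frags = topology_fragments(parse_glycan_topology("HexNAc"))
        kinds = sorted((f.kind, f.composition.size) for f in frags)
        assert kinds == [("B", 1), ("Y", 0), ("Y", 1)]

    def test_matches_brute_force_oracle_on_small_trees(self):
        """Enumeration equals an independent connected-subgraph oracle on
        every random tree shape up to 8 nodes."""
        rng = random.Random(42)
        for n in range(1, 9):
            for _ in range(8):
                tree = _random_tree(rng, n)
                oracle = {(k, frozenset(c)) for k, _, c in _oracle_fragments(tree)}
                mine = {(f.kind, frozenset(f.broken_bonds)) for f in topology_fragments(tree)}
                assert mine == oracle, tree.text()

    def test_max_breaks_filter(self):
        t = parse_glycan_topology("Hex(Hex,Hex,Hex)")
        all_frags = topology_fragments(t)
        limited = topology_fragments(t, max_breaks=1)
        assert {f.n_breaks for f in limited} <= {0, 1}
        assert len(limited) < len(all_frags)

    def test_single_break_mass_conservation(self):
        """Cutting one bond: mass(B side) + mass(Y side) = intact glycopeptide."""
        tree = parse_glycan_topology("HexNAc(HexNAc(Hex(Hex(Hex),Hex(NeuAc))))")
        peptide = (AMINO_ACIDS["K"] + AMINO_ACIDS["N"] + WATER)
        intact = peptide.mass + tree.formula().mass
        frags = topology_fragments(tree, peptide_formula=peptide)
        singles_b = {f.broken_bonds[0]: f for f in frags
                     if f.kind == "B" and len(f.broken_bonds) == 1}
        singles_y = {f.broken_bonds[0]: f for f in frags
                     if f.kind == "Y" and len(f.broken_bonds) == 1}
        assert singles_b and set(singles_b) <= set(range(tree.n_nodes))
        for edge, b_frag in singles_b.items():
            y_frag = singles_y[edge]
            assert b_frag.glycan_formula.mass + y_frag.glycan_formula.mass == \
                pytest.approx(intact, abs=1e-9)

    def test_composition_mode_masses_superset_of_topology(self):
        tree = parse_glycan_topology("HexNAc(HexNAc(Hex(Hex,Hex)))")
        topo_masses = {round(f.glycan_formula.mass, 6)
                       for f in topology_fragments(tree) if f.kind == "B"}
        b, _ = composition_fragments(tree.composition())
        comp_masses = {round(f.glycan_formula.mass, 6) for f in b if f.composition.size}
        assert topo_masses <= comp_masses


class TestDiagnosticIons:
    def test_hexnac(self):
        ions = dict(glycan_diagnostic_ions(["HexNAc"]))
        assert ions["oxonium:HexNAc"] == pytest.approx(204.086650, abs=1e-4)
        assert ions["oxonium:HexNAc-H2O1"] == pytest.approx(186.076085, abs=1e-4)

    def test_hex(self):
        ions = dict(glycan_diagnostic_ions(["Hex"]))
        assert ions["oxonium:Hex"] == pytest.approx(163.060102, abs=1e-4)

    def test_empty(self):
        assert glycan_diagnostic_ions([]) == []
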
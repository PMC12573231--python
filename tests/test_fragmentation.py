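import random

import pytest

from specannot.chem import AMINO_ACIDS, PROTON_MASS, WATER, parse_formula
from specannot.fragmentation import (
    FragmentationModel,
    MODEL_PRESETS,
    SeriesSettings,
    backbone_fragments,
    generate_fragments,
    get_model,
    immonium_fragments,
    precursor_fragments,
    satellite_fragments,
)
from specannot.proforma import parse_proforma


def by_label(frags, label):
    return [f for f in frags if f.label == label]


class TestBackbone:
    def test_peptide_b2_y1(self, registry, bare_model):
        cp = parse_proforma("PEPTIDE", registry)
        frags = backbone_fragments(cp, bare_model, 1)
        (b2,) = by_label(frags, "b2")
        assert b2.neutral_mass == pytest.approx(226.095350, abs=1e-4)
        assert b2.mz == pytest.approx(227.102626, abs=1e-4)
        (y1,) = by_label(frags, "y1")
        assert y1.neutral_mass == pytest.approx(147.053157, abs=1e-5)
        assert y1.mz == pytest.approx(148.060434, abs=1e-5)

    def test_a_equals_b_minus_co(self, registry):
        model = get_model("uvpd")
        cp = parse_proforma("PEPTIDEK", registry)
        frags = [f for f in backbone_fragments(cp, model, 1)
                 if not f.losses and f.charge == 1]
        a = {f.position: f.neutral_mass for f in frags if f.kind == "a"}
        b = {f.position: f.neutral_mass for f in frags if f.kind == "b"}
        for i in a:
            assert b[i] - a[i] == pytest.approx(27.994915, abs=1e-6)

    def test_complementarity_identities(self, registry, bare_model):
        """b_i + y_{n-i} = M and c_i + z_{n-i} = M, to 1e-9 Da."""
        rng = random.Random(0)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            seq = "".join(rng.choice(alphabet) for _ in range(rng.randint(3, 25)))
            cp = parse_proforma(seq, registry)
            pep = cp.peptidoforms[0]
            m = pep.neutral_mass
            frags = [f for f in backbone_fragments(cp, bare_model, 1)
                     if f.charge == 1 and not f.losses]
            series = {k: {f.position: f.neutral_mass for f in frags if f.kind == k}
                      for k in "bcyz"}
            n = len(seq)
            for i in range(1, n):
                assert series["b"][i] + series["y"][n - i] == pytest.approx(m, abs=1e-9)
                assert series["c"][i] + series["z"][n - i] == pytest.approx(m, abs=1e-9)

    def test_all_series_disabled_gives_nothing(self, registry):
        cp = parse_proforma("PEPTIDE", registry)
        assert backbone_fragments(cp, FragmentationModel(), 1) == []

    def test_losses_add_variants(self, registry):
        cp = parse_proforma("PEPS[Phospho]K/2", registry)
        frags = backbone_fragments(cp, get_model("cid_hcd"), 2)
        b4 = [f for f in frags if f.kind == "b" and f.position == 4 and f.charge == 1]
        losses = {f.losses for f in b4}
        assert ("-H3O4P1",) in losses  # phospho neutral loss on fragments spanning S4
        b2 = [f for f in frags if f.kind == "b" and f.position == 2 and f.charge == 1]
        assert ("-H3O4P1",) not in {f.losses for f in b2}


class TestSatellites:
    def test_v1_of_leucine_is_glycine_equivalent(self, registry):
        cp = parse_proforma("GGL", registry)
        frags = satellite_fragments(cp, get_model("uvpd"), 1)
        v1 = [f for f in frags if f.kind == "v" and f.position == 1 and not f.losses]
        assert v1[0].mz == pytest.approx(76.039305, abs=1e-5)

    def test_isoleucine_d1_variants_differ_by_ch2(self, registry):
        cp = parse_proforma("IGG", registry)
        frags = satellite_fragments(cp, get_model("uvpd"), 1)
        d1 = sorted(f.neutral_mass for f in frags
                    if f.kind == "d" and f.position == 1 and not f.losses)
        assert len(d1) == 2
        assert d1[1] - d1[0] == pytest.approx(14.015650, abs=1e-5)

    def test_glycine_has_no_d_ions(self, registry):
        cp = parse_proforma("GAG", registry)
        frags = satellite_fragments(cp, get_model("uvpd"), 1)
        assert not [f for f in frags if f.kind == "d" and f.position == 1]

    def test_w_is_zdot_minus_distal(self, registry):
        cp = parse_proforma("GGV", registry)
        model = get_model("uvpd")
        sats = satellite_fragments(cp, model, 1)
        (w1,) = [f for f in sats if f.kind == "w" and f.position == 1 and not f.losses]
        back = backbone_fragments(cp, get_model("etd"), 1)
        (z1,) = [f for f in back if f.kind == "z" and f.position == 1 and not f.losses]
        # z from the etd preset is the z-dot radical (z+1)
        assert z1.neutral_mass - w1.neutral_mass == pytest.approx(
            parse_formula("C1H3").mass, abs=1e-6)


class TestImmonium:
    @pytest.mark.parametrize("aa,expected", [
        ("L", 86.096426), ("I", 86.096426), ("G", 30.033826), ("P", 70.065126),
    ])
    def test_known_values(self, registry, aa, expected):
        cp = parse_proforma(aa * 2, registry)
        (imm,) = immonium_fragments(cp)
        assert imm.mz == pytest.approx(expected, abs=1e-4)

    def test_modified_residue_distinct(self, registry):
        cp = parse_proforma("MM[Oxidation]", registry)
        imms = immonium_fragments(cp)
        assert len(imms) == 2
        masses = sorted(f.mz for f in imms)
        assert masses[1] - masses[0] == pytest.approx(15.994915, abs=1e-5)


class TestPrecursor:
    def test_peptide_charges(self, registry, bare_model):
        cp = parse_proforma("PEPTIDE/2", registry)
        frags = precursor_fragments(cp, bare_model, 2)
        plain = {f.charge: f.mz for f in frags if not f.losses}
        assert plain[2] == pytest.approx(400.687258, abs=1e-5)
        assert plain[1] == pytest.approx(800.367240, abs=1e-5)

    def test_phospho_loss_variant(self, registry):
        cp = parse_proforma("PEPS[Phospho]K/2", registry)
        frags = precursor_fragments(cp, get_model("cid_hcd"), 2)
        deltas = {round(a.neutral_mass - b.neutral_mass, 5)
                  for a in frags for b in frags if a.charge == b.charge}
        assert any(abs(d - 97.97690) < 1e-3 for d in deltas)

    def test_chimeric_members_tagged(self, registry, bare_model):
        cp = parse_proforma("AAA+GGG", registry)
        frags = precursor_fragments(cp, bare_model, 1)
        assert {f.peptidoform_index for f in frags} == {0, 1}


class TestCrossLinks:
    def test_spanning_fragment_variants(self, registry):
        """A c ion spanning the linked Cys: 1 intact + 3 breakage variants."""
        cp = parse_proforma("SEC[XL:Disulfide#XL1]K+ACK[#XL1]", registry)
        frags = backbone_fragments(cp, get_model("etd"), 2)
        c3 = [f for f in frags if f.kind == "c" and f.peptidoform_index == 0
              and f.position == 3 and f.charge == 1 and not f.losses]
        assert len(c3) == 4
        variants = {f.variant for f in c3}
        assert any("H-2S-1:S1" in v for v in variants)
        assert sum("xl:XL1" == v for v in variants) == 1  # the intact variant

    def test_intact_variant_carries_partner_mass(self, registry):
        cp = parse_proforma("SEC[XL:Disulfide#XL1]K+ACK[#XL1]", registry)
        frags = backbone_fragments(cp, get_model("etd"), 1)
        c3 = {f.variant: f.neutral_mass for f in frags
              if f.kind == "c" and f.peptidoform_index == 0 and f.position == 3
              and not f.losses}
        partner = parse_proforma("ACK", registry).peptidoforms[0].neutral_mass
        linker = registry.get("Disulfide").formula.mass
        assert c3["xl:XL1"] - c3["xl:XL1:H-1:H1"] == pytest.approx(
            partner + linker - parse_formula("H-1").mass, abs=1e-6)

    def test_s_transfer_rule_conserves_complex_mass(self, registry):
        """c_i (link broken, retained) + z_{n-i} + partner (with partner stub)
        reassemble the intact complex for the S-transfer rule."""
        cp = parse_proforma("SEC[XL:Disulfide#XL1]K+ACK[#XL1]", registry)
        pep1 = parse_proforma("SECK", registry).peptidoforms[0].neutral_mass
        pep2 = parse_proforma("ACK", registry).peptidoforms[0].neutral_mass
        linker = registry.get("Disulfide").formula.mass
        intact_complex = pep1 + pep2 + linker
        frags = backbone_fragments(cp, get_model("etd"), 1)
        c3 = {f.variant: f.neutral_mass for f in frags
              if f.kind == "c" and f.peptidoform_index == 0 and f.position == 3
              and not f.losses}
        # plain z1 of chain 1 (does not span the link site)
        (z1,) = [f for f in frags if f.kind == "z" and f.peptidoform_index == 0
                 and f.position == 1 and not f.losses and "+1H" in f.variant]
        z1_plain = z1.neutral_mass - parse_formula("H1").mass  # undo the z-dot H
        retained = parse_formula("H-2S-1")
        partner_stub = parse_formula("S1")
        total = c3[f"xl:XL1:{retained.text()}:{partner_stub.text()}"] + z1_plain \
            + pep2 + partner_stub.mass
        # c + z = M + NH3 - NH3 = M; so total should equal the intact complex
        assert total == pytest.approx(intact_complex, abs=1e-6)

    def test_intra_loop_positions_suppressed_without_breakage(self, registry, tmp_path):
        """A non-cleavable intra-chain link makes in-loop cleavages fragment-free."""
        import json
        custom = [{"name": "NClink", "formula": "H-2", "targets": ["C"], "linker": True}]
        path = tmp_path / "mods.json"
        path.write_text(json.dumps(custom))
        from specannot.modifications import load_modification_registry
        reg = load_modification_registry([path])
        cp = parse_proforma("AC[XL:NClink#XL1]GGC[#XL1]K", reg)
        frags = backbone_fragments(cp, get_model("bare"), 1)
        positions = {f.position for f in frags if f.kind == "b"}
        # cleavages between the two linked Cys (positions 2..4) are cyclic
        assert positions == {1, 5}

    def test_cleavable_intra_loop_produces_breakage_only(self, registry):
        cp = parse_proforma("AC[XL:Disulfide#XL1]GGC[#XL1]K", registry)
        frags = backbone_fragments(cp, get_model("bare"), 1)
        in_loop = [f for f in frags if f.kind == "b" and f.position == 3]
        assert in_loop and all("xl:XL1:" in f.variant for f in in_loop)


class TestGenerateFragments:
    def test_ag_by_model_counts(self, registry):
        model = FragmentationModel(series={
            "b": SeriesSettings(enabled=True, charges=(1, 1)),
            "y": SeriesSettings(enabled=True, charges=(1, 1)),
        }, diagnostic_ions=False)
        cp = parse_proforma("AG", registry)
        frags = generate_fragments(cp, model, 1)
        backbone = [f for f in frags if f.kind in "by"]
        precursor = [f for f in frags if f.kind == "precursor"]
        assert len(backbone) == 2 and len(precursor) == 1
        assert len(frags) == 3

    def test_empty_model_precursor_only(self, registry):
        cp = parse_proforma("PEPTIDE", registry)
        frags = generate_fragments(cp, FragmentationModel(), 1)
        assert frags and all(f.kind == "precursor" for f in frags)

    def test_monotonic_in_enabled_series(self, registry):
        cp = parse_proforma("PEPTIDEK/2", registry)
        small = FragmentationModel(series={"b": SeriesSettings(enabled=True)})
        bigger = FragmentationModel(series={
            "b": SeriesSettings(enabled=True),
            "y": SeriesSettings(enabled=True, losses=(parse_formula("H2O1"),)),
        })
        ids_small = {f.identity() for f in generate_fragments(cp, small, 2)}
        ids_big = {f.identity() for f in generate_fragments(cp, bigger, 2)}
        assert ids_small <= ids_big

    def test_mz_matches_formula_bookkeeping(self, registry, ethcd_model):
        """Every formula-backed m/z re-derives from its own neutral formula."""
        cp = parse_proforma("PEPTM[Oxidation]IDEK/2", registry)
        for f in generate_fragments(cp, ethcd_model, 2):
            if f.formula is not None:
                pep = cp.peptidoforms[f.peptidoform_index]
                expected = f.formula.with_isotope_substitution(pep.isotopes).mass
                assert f.neutral_mass == pytest.approx(expected, abs=1e-9)
                assert f.mz == pytest.approx(
                    (expected + f.charge * PROTON_MASS) / f.charge, abs=1e-9)

    def test_glycopeptide_includes_oxonium_and_y(self, registry):
        cp = parse_proforma("PEPTN[Glycan:HexNAc1Hex1]K/2", registry)
        frags = generate_fragments(cp, get_model("cid_hcd"), 2)
        b_mzs = [f.mz for f in frags if f.kind == "glycan_B" and f.charge == 1]
        assert any(abs(m - 204.086650) < 1e-4 for m in b_mzs)
        y = [f for f in frags if f.kind == "glycan_Y"]
        assert y  # peptide+core fragments present

    def test_labile_glycan_not_on_backbone(self, registry):
        plain = parse_proforma("PEPTIDE", registry)
        labile = parse_proforma("{Glycan:Hex1}PEPTIDE", registry)
        model = get_model("cid_hcd")
        b_plain = {(f.kind, f.position, f.charge, round(f.neutral_mass, 6))
                   for f in backbone_fragments(plain, model, 1)}
        b_labile = {(f.kind, f.position, f.charge, round(f.neutral_mass, 6))
                    for f in backbone_fragments(labile, model, 1)}
        assert b_plain == b_labile


class TestModels:
    @pytest.mark.parametrize("name", MODEL_PRESETS)
    def test_presets_resolve(self, name):
        model = get_model(name)
        assert model.name in (name, "cid_hcd", "bare")

    def test_bare_is_bcyz_no_losses(self):
        model = get_model("bare")
        assert sorted(model.enabled_series()) == ["b", "c", "y", "z"]
        assert all(not s.losses for s in model.series.values())

    def test_json_round_trip(self, tmp_path):
        model = get_model("ethcd")
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = FragmentationModel.from_json(path)
        assert loaded.to_dict() == model.to_dict()

    def test_etd_z_is_radical(self):
        model = get_model("etd")
        assert model.series_settings("z").h_variants == (1,)
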
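"""Backbone extraction, AA/AB classification, the ring-opening exception,
end-group search and BigSMILES assembly."""

import re

import pytest

from polybigsmiles import smiles_core as sc
from polybigsmiles.classify_convert import (classify, convert,
                                            default_pattern_table,
                                            detect_ring_opening,
                                            extract_main_chain,
                                            find_end_groups,
                                            make_two_unit_variant)
from polybigsmiles.errors import RejectedInput

_SHAPES = {
    "AA": re.compile(r"^\{\$[^${}<>,]+\$\}$"),
    "AB_plain": re.compile(r"^\{<[^${}<>,]+>\}$"),
    "AB_split": re.compile(r"^\{<[^${}<>,]+<,>[^${}<>,]+>\}$"),
    "AB_two_unit": re.compile(r"^\{<[^${}<>,]+>,<[^${}<>,]+>\}$"),
}


class TestMainChain:
    @pytest.mark.parametrize("core, elements", [
        ("CC(OC(=O)CCC)", ("C", "C")),
        ("OCCOC(=O)CCCCC(=O)", ("O", "C", "C", "O", "C", "C", "C", "C",
                                "C", "C")),
        ("CC(COC)O", ("C", "C", "O")),
        ("CC(n1c2ccccc2c2ccccc12)", ("C", "C")),
    ])
    def test_depth_zero_atoms(self, core, elements):
        assert extract_main_chain(core).elements == elements

    def test_aromatic_flags_kept(self):
        mc = extract_main_chain("c1ccc(cc1)C")
        assert mc.atoms[0] == ("C", True) and mc.atoms[-1] == ("C", False)


class TestClassify:
    @pytest.mark.parametrize("core, ptype", [
        ("CC(OC(=O)CCC)", "AA"),
        ("OCCOC(=O)CCCCC(=O)", "AB"),
        ("C[Si](C)(C)C", "AA"),      # carbosilane backbone
        ("CCCO", "AB"),
    ])
    def test_backbone_rule(self, core, ptype):
        assert classify(extract_main_chain(core)) == ptype


class TestRingOpening:
    @pytest.mark.parametrize("core, flag", [
        ("CC(COC)O", True),
        ("CCCO", False),            # length 4
        ("CC(C)O", True),
        ("OCC", True),              # reversed orientation accepted
    ])
    def test_detection(self, core, flag):
        assert detect_ring_opening(extract_main_chain(core)) is flag

    @pytest.mark.parametrize("core, variant", [
        ("CC(COC)O", "C(COC)CO"),
        ("CC(C)O", "C(C)CO"),
    ])
    def test_two_unit_variant(self, core, variant):
        out = make_two_unit_variant(core)
        assert out == variant
        assert sc.cycle_key(f"*{out}*") == sc.cycle_key(f"*{core}*")

    def test_symmetric_unit_has_no_distinct_variant(self):
        assert make_two_unit_variant("CCO") is None


class TestEndGroupSearch:
    def test_adipate_splits_at_zero_displacement(self):
        split = find_end_groups("OCCOC(=O)CCCCC(=O)")
        assert (split.group_a, split.group_b) == \
            ("OCCO", "C(=O)CCCCC(=O)")
        assert split.rotation_used == 0

    def test_rotated_core_found_only_with_full_search(self):
        core = "C(=O)CCCCC(=O)OCCO"
        split = find_end_groups(core, move_parallel=-1)
        assert (split.group_a, split.group_b) == \
            ("OCCO", "C(=O)CCCCC(=O)")
        assert split.rotation_used > 0
        assert find_end_groups(core, move_parallel=0) is None

    def test_aromatic_backbone_without_end_groups(self):
        core = relocate_core(
            "*c1ccc(-c2ccc(-c3ccc(-c4cnc5ccc(-c6ccc7ncc(*)nc7c6)cc5n4)"
            "cc3)cc2)cc1")
        assert find_end_groups(core) is None

    def test_split_reassembles_to_same_polymer(self):
        split = find_end_groups("OCCOC(=O)CCCCC(=O)")
        joined = f"*{split.group_a}{split.group_b}*"
        assert sc.cycle_key(joined) == sc.cycle_key("*OCCOC(=O)CCCCC(=O)*")

    def test_amide_pair_recognized(self):
        # nylon-6,6 repeat unit: diamine + diacid
        split = find_end_groups("NCCCCCCNC(=O)CCCCC(=O)")
        assert split.pattern == "amide"
        assert split.group_a == "NCCCCCCN"


def relocate_core(s):
    from polybigsmiles.preprocess import relocate_asterisks
    return relocate_asterisks(s).core


class TestConvert:
    @pytest.mark.parametrize("s, expected", [
        ("*CC(*)(C)C(=O)OCC(C)C", "{$CC(C(=O)OCC(C)C)(C)$}"),
        ("*CC(COC)O*", "{<CC(COC)O>,<C(COC)CO>}"),
        ("*OCCOC(=O)CCCCC(=O)*", "{<OCCO<,>C(=O)CCCCC(=O)>}"),
        ("*CC(OC( = O)CCC)*", "{$CC(OC(=O)CCC)$}"),
    ])
    def test_known_outputs(self, s, expected):
        assert convert(s).text == expected

    def test_wildcardless_input_rejected(self):
        with pytest.raises(RejectedInput) as exc:
            convert("OCCOC(=O)CCCCC(=O)")
        assert exc.value.reason == "wrong_point_count"
        assert exc.value.detail == 0

    def test_variant_matches_string_shape(self, fixture_units):
        for s in fixture_units:
            rec = convert(s)
            assert _SHAPES[rec.variant].match(rec.text), \
                (rec.variant, rec.text)

    def test_dollar_iff_carbon_silicon_backbone(self, fixture_units):
        for s in fixture_units:
            rec = convert(s)
            backbone_aa = all(
                e in ("C", "Si")
                for e in extract_main_chain(rec.source_core).elements)
            assert ("$" in rec.text) == backbone_aa

    def test_deterministic(self):
        s = "*CC(*)(C)C(=O)OCC(C)C"
        assert convert(s).text == convert(s).text

    def test_custom_table_order_respected(self):
        table = default_pattern_table()
        assert [e.name for e in table.entries] == \
            ["carbonate", "urethane", "ester", "amide"]
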
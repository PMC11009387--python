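"""BigSMILES shape parsing, back-conversion and structural equivalence."""

import pytest

from polybigsmiles import smiles_core as sc
from polybigsmiles.bigsmiles_parse import (parse_bigsmiles,
                                           structurally_equivalent,
                                           to_smiles)
from polybigsmiles.classify_convert import convert
from polybigsmiles.errors import BigSmilesSyntaxError


class TestParse:
    def test_aa_shape(self):
        p = parse_bigsmiles("{$CC(OC(=O)CCC)$}")
        assert p.variant == "AA" and p.units == ("CC(OC(=O)CCC)",)

    def test_split_shape(self):
        p = parse_bigsmiles("{<OCCO<,>C(=O)CCCCC(=O)>}")
        assert p.variant == "AB_split"
        assert p.units == ("OCCO", "C(=O)CCCCC(=O)")

    def test_two_unit_shape(self):
        p = parse_bigsmiles("{<CC(COC)O>,<C(COC)CO>}")
        assert p.variant == "AB_two_unit"
        assert p.units == ("CC(COC)O", "C(COC)CO")

    def test_typeset_whitespace_tolerated(self):
        p = parse_bigsmiles("{<OCCO <, > C( = O)CCCCC( = O) >}")
        assert p.variant == "AB_split"

    def test_version_11_descriptors_normalized(self):
        assert parse_bigsmiles("{[$]CC[$]}").variant == "AA"
        assert parse_bigsmiles("{[<]CCO[>]}").variant == "AB_plain"

    @pytest.mark.parametrize("bad", [
        "{$CC(OC(=O)CCC$}",          # unbalanced fragment
        "{$CC>}",                    # mixed descriptors
        "{<CC>",                     # unbalanced curly bracket
        "CC",                        # no stochastic object
        "{<CC<,>C<,>C>}",            # too many separators
    ])
    def test_rejects_unknown_layouts(self, bad):
        with pytest.raises(BigSmilesSyntaxError):
            parse_bigsmiles(bad)


class TestToSmiles:
    @pytest.mark.parametrize("b, s", [
        ("{$CC(OC(=O)CCC)$}", "*CC(OC(=O)CCC)*"),
        ("{<OCCO<,>C(=O)CCCCC(=O)>}", "*OCCOC(=O)CCCCC(=O)*"),
        ("{<CC(COC)O>,<C(COC)CO>}", "*CC(COC)O*"),
    ])
    def test_back_conversion(self, b, s):
        out = to_smiles(b)
        assert out == s
        assert sc.validate_grammar(out).ok
        assert sc.wildcard_count(out) == 2


class TestStructuralEquivalence:
    def test_branch_order_is_irrelevant(self):
        assert structurally_equivalent("{$CC(C(=O)OCC(C)C)(C)$}",
                                       "{$CC(C)(C(=O)OCC(C)C)$}")

    def test_aa_vs_ab_descriptors_disagree(self):
        assert not structurally_equivalent("{$CC$}", "{<CC>}")

    def test_smiles_vs_bigsmiles(self):
        assert structurally_equivalent("*CCOC*", "{<CCCO>}")

    def test_converted_fixtures_match_ground_truth(self, table1_records):
        for rec in table1_records:
            out = convert(rec.normalized_reference)
            assert structurally_equivalent(out.text,
                                           rec.expected_bigsmiles), rec.name

    def test_erroneous_records_fail_parse_or_equivalence(
            self, table1_records):
        # three published errors are not even feasible structures; the
        # other five describe different polymers
        n_unparseable = 0
        for rec in table1_records:
            try:
                eq = structurally_equivalent(rec.erroneous_bigsmiles,
                                             rec.expected_bigsmiles)
            except BigSmilesSyntaxError:
                n_unparseable += 1
                continue
            assert not eq, rec.name
        assert n_unparseable == 3


class TestInverse:
    def test_roundtrip_preserves_cycle_key(self, fixture_units):
        for s in fixture_units:
            rec = convert(s)
            back = to_smiles(rec.text)
            assert sc.cycle_key(back) == sc.cycle_key(s)
            cls = rec.classification
            rotation = cls.split.rotation_used if cls and cls.split else 0
            if rotation == 0 and rec.variant != "AB_two_unit":
                assert sc.unit_key(back) == \
                    sc.unit_key(f"*{rec.source_core}*")

    def test_parse_inverts_assembly(self, fixture_units):
        for s in fixture_units:
            rec = convert(s)
            parsed = parse_bigsmiles(rec.text)
            assert parsed.variant == rec.variant
            if rec.variant in ("AA", "AB_plain"):
                assert parsed.units == (rec.source_core,)
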
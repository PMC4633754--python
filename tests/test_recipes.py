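import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mediarec import MediarecError
from mediarec.recipes import (
    RecipeError,
    VariantInstruction,
    compile_medium,
    expand_variants,
    parse_recipe,
    resolve_volume,
    to_standard_units,
    unpack_references,
    variant_instructions_from_tags,
)


class TestParse:
    def test_hydrated_salt_line(self):
        r = parse_recipe("/notag/ CaCl2 x 2 H2O @ 10 mg", "M1")
        assert len(r.lines) == 1
        line = r.lines[0]
        assert (line.raw_name, line.amount, line.raw_unit) == ("CaCl2 x 2 H2O", 10.0, "mg")

    def test_empty_text_gives_empty_recipe(self):
        r = parse_recipe("", "M1")
        assert r.lines == [] and r.tags == [] and r.referenced_media == []

    def test_ph_tag_sets_ph_not_ingredient(self):
        r = parse_recipe("/ph/ 7.2", "M1")
        assert r.ph == 7.2
        assert r.lines == []

    def test_unknown_tag_names_line(self):
        with pytest.raises(RecipeError, match="line 2"):
            parse_recipe("NaCl @ 5 g\n/bogus/ stuff", "M1")

    def test_malformed_amount_reported(self):
        with pytest.raises(RecipeError, match="amount"):
            parse_recipe("NaCl @ five g", "M1")

    def test_reference_and_volume_lines(self):
        r = parse_recipe("ref: M2 @ 100 ml\nvolume: 0.5 l", "M1")
        assert r.referenced_media == [("M2", 100.0, "ml")]
        assert r.declared_volume == (0.5, "l")


class TestVariants:
    def test_remove_variant_gets_suffixed_id(self):
        base = parse_recipe("NaCl @ 5 g\nglucose @ 2 g", "M1")
        variants = expand_variants(
            base, [VariantInstruction("1", (("remove", "NaCl"),))]
        )
        assert [v.medium_id for v in variants] == ["M1", "M1.1"]
        assert all(l.raw_name != "NaCl" for l in variants[1].lines)

    def test_no_instructions_identity(self):
        base = parse_recipe("NaCl @ 5 g", "M1")
        assert expand_variants(base, []) == [base]

    def test_set_concentration(self):
        base = parse_recipe("glucose @ 5 g", "M1")
        (_, var) = expand_variants(
            base,
            [VariantInstruction("1", (("set_concentration", "glucose", 10.0, "g"),))],
        )
        assert var.lines[0].amount == 10.0

    def test_edit_of_absent_compound_names_it(self):
        base = parse_recipe("NaCl @ 5 g", "M1")
        with pytest.raises(RecipeError, match="glucose"):
            expand_variants(base, [VariantInstruction("1", (("remove", "glucose"),))])

    def test_tags_convert_to_instructions(self):
        base = parse_recipe("NaCl @ 5 g\n/rm/ NaCl\n/replace/ NaCl => KCl", "M1")
        instructions = variant_instructions_from_tags(base)
        assert [i.edits[0][0] for i in instructions] == ["remove", "replace"]
        variants = expand_variants(base, instructions)
        assert len(variants) == 3


class TestVolume:
    def test_no_declared_volume_fills(self):
        r = parse_recipe("NaCl @ 5 g", "M1")
        res = resolve_volume(r)
        assert (res.mode, res.multiplier) == ("fill", 1.0)

    def test_half_litre_scales_to_two(self):
        r = parse_recipe("volume: 0.5 l", "M1")
        res = resolve_volume(r)
        assert res.mode == "scale"
        assert res.multiplier == pytest.approx(2.0)

    def test_override_wins_over_declared_volume(self):
        r = parse_recipe("volume: 1.2 l", "M1")
        res = resolve_volume(r, overrides={"M1": "fill"})
        assert (res.mode, res.multiplier) == ("fill", 1.0)

    def test_scale_with_zero_volume_rejected(self):
        r = parse_recipe("volume: 0 l", "M1")
        with pytest.raises(RecipeError):
            resolve_volume(r, overrides={"M1": "scale"})


class TestUnpack:
    def test_nested_volumes_multiply_through(self):
        # two nesting levels with the 1 g/ml density rule for compound volume
        rs = {
            "a": parse_recipe("ref: b @ 10 ml", "a"),
            "b": parse_recipe("ref: c @ 15 ml", "b"),
            "c": parse_recipe("metabolite X @ 5 ml", "c"),
        }
        flat = unpack_references(rs["a"], rs)
        assert len(flat) == 1
        assert flat[0].raw_name == "metabolite X"
        assert flat[0].amount == pytest.approx(0.00075, rel=1e-12)

    def test_submedium_concentration_times_volume(self):
        rs = {
            "main": parse_recipe("ref: sub @ 100 ml", "main"),
            "sub": parse_recipe("NaCl @ 5 g/l", "sub"),
        }
        flat = unpack_references(rs["main"], rs)
        assert flat[0].amount == pytest.approx(0.5, rel=1e-12)

    def test_no_references_identity(self):
        r = parse_recipe("NaCl @ 5 g\nglucose @ 2 g", "M1")
        flat = unpack_references(r, {"M1": r})
        assert {(e.raw_name, e.amount) for e in flat} == {("NaCl", 5.0), ("glucose", 2.0)}

    def test_duplicate_compound_across_levels_summed(self):
        rs = {
            "main": parse_recipe("NaCl @ 1 g\nref: sub @ 500 ml", "main"),
            "sub": parse_recipe("NaCl @ 4 g/l", "sub"),
        }
        flat = unpack_references(rs["main"], rs)
        assert len(flat) == 1
        assert flat[0].amount == pytest.approx(3.0)

    def test_cycle_detected_and_listed(self):
        rs = {
            "a": parse_recipe("ref: b @ 10 ml", "a"),
            "b": parse_recipe("ref: a @ 10 ml", "b"),
        }
        with pytest.raises(RecipeError, match="a -> b -> a"):
            unpack_references(rs["a"], rs)

    def test_missing_reference_rejected(self):
        r = parse_recipe("ref: ghost @ 10 ml", "a")
        with pytest.raises(RecipeError, match="ghost"):
            unpack_references(r, {"a": r})

    def test_unpacking_associative(self, compounds):
        """Flattening nested references equals flattening innermost-first."""
        rs = {
            "a": parse_recipe("NaCl @ 1 g\nref: b @ 200 ml", "a"),
            "b": parse_recipe("glucose @ 5 g\nref: c @ 100 ml", "b"),
            "c": parse_recipe("NaCl @ 10 g/l", "c"),
        }
        direct = {e.raw_name: e.amount for e in unpack_references(rs["a"], rs)}
        # innermost-first: inline c into b numerically, then b into a
        b_flat = {e.raw_name: e.amount for e in unpack_references(rs["b"], rs)}
        manual = {"NaCl": 1.0 + 0.2 * b_flat["NaCl"], "glucose": 0.2 * b_flat["glucose"]}
        for name, amount in manual.items():
            assert direct[name] == pytest.approx(amount, rel=1e-12)


class TestStandardUnits:
    def test_hydrated_calcium_chloride_to_ions(self, compounds):
        r = parse_recipe("/notag/ CaCl2 x 2 H2O @ 10 mg", "M1")
        comps = to_standard_units(unpack_references(r, {"M1": r}), compounds)
        amounts = {c.component_id: c.amount for c in comps}
        assert amounts["Ca2+"] == pytest.approx(0.010 / 147.01, rel=1e-6)
        assert amounts["Cl-"] == pytest.approx(2 * 0.010 / 147.01, rel=1e-6)

    def test_trace_flag_passes_without_concentration(self, compounds):
        r = parse_recipe("FeSO4 x 7 H2O @ 1 trace", "M1")
        comps = to_standard_units(unpack_references(r, {"M1": r}), compounds)
        assert comps[0].kind == "trace"
        assert comps[0].amount is None

    def test_direct_molar_entry_unchanged(self, compounds):
        r = parse_recipe("NaCl @ 0.25 M", "M1")
        comps = to_standard_units(unpack_references(r, {"M1": r}), compounds)
        amounts = {c.component_id: c.amount for c in comps}
        assert amounts["Na+"] == pytest.approx(0.25)

    def test_missing_molecular_weight_rejected(self, compounds):
        broken = dict(compounds)
        from mediarec import CompoundRecord

        broken["mystery"] = CompoundRecord(
            "mystery", "mystery", constituents=(("mystery", 1),)
        )
        r = parse_recipe("mystery @ 1 g", "M1")
        with pytest.raises(RecipeError, match="molecular weight"):
            to_standard_units(unpack_references(r, {"M1": r}), broken)

    def test_unknown_unit_rejected(self):
        r = parse_recipe("NaCl @ 5 cubits", "M1")
        with pytest.raises(RecipeError, match="cubits"):
            unpack_references(r, {"M1": r})


class TestCompile:
    def test_mole_of_salt_per_litre(self, compounds):
        r = parse_recipe("NaCl @ 58.44 g", "M1")
        mv = compile_medium("M1", {"M1": r}, compounds)
        assert mv.amount_of("Na+") == pytest.approx(1.0)
        assert mv.amount_of("Cl-") == pytest.approx(1.0)
        assert mv.is_defined

    def test_submedium_dilution(self, compounds):
        rs = {
            "main": parse_recipe("ref: brine @ 100 ml", "main"),
            "brine": parse_recipe("NaCl @ 58.44 g/l", "brine"),
        }
        mv = compile_medium("main", rs, compounds)
        assert mv.amount_of("Na+") == pytest.approx(0.1)

    def test_complex_component_in_g_per_l(self, compounds):
        mv = compile_medium(
            "M1", {"M1": parse_recipe("peptone @ 5 g\n/ph/ 7.0", "M1")}, compounds
        )
        assert mv.amount_of("complex-meat") == pytest.approx(5.0)
        assert not mv.is_defined
        assert mv.ph == 7.0

    def test_scale_multiplies_composition(self, compounds):
        r = parse_recipe("NaCl @ 29.22 g\nvolume: 0.5 l", "M1")
        mv = compile_medium("M1", {"M1": r}, compounds)
        assert mv.amount_of("Na+") == pytest.approx(1.0)

    def test_line_order_invariance(self, compounds):
        lines = ["NaCl @ 5 g", "glucose @ 2 g", "peptone @ 1 g", "KCl @ 0.3 g"]
        rng = random.Random(0)
        reference = None
        for _ in range(5):
            rng.shuffle(lines)
            mv = compile_medium(
                "M1", {"M1": parse_recipe("\n".join(lines), "M1")}, compounds
            )
            snapshot = tuple((c.component_id, c.kind, c.amount) for c in mv.components)
            if reference is None:
                reference = snapshot
            assert snapshot == reference

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(grams=st.floats(min_value=1e-6, max_value=1e3))
    def test_mass_conservation(self, grams):
        """grams in == moles out x molecular weight, to 1e-9 relative."""
        from mediarec.recipes import default_compound_table

        compounds = default_compound_table()
        rec = compounds["CaCl2 x 2 H2O"]
        r = parse_recipe(f"CaCl2 x 2 H2O @ {grams!r} g", "M1")
        mv = compile_medium("M1", {"M1": r}, compounds)
        moles_raw = mv.amount_of("Ca2+")  # ratio 1
        assert moles_raw * rec.molecular_weight == pytest.approx(grams, rel=1e-9)
        assert mv.amount_of("Cl-") == pytest.approx(2 * moles_raw, rel=1e-12)
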
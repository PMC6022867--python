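import pytest

from cycmotif.motif import (Motif, MotifElement, MotifParseError,
                            ResidueClass, Role, add_upstream_anchor,
                            constrain_wildcard, motif_to_string, parse_motif,
                            preset, preset_catalogue, preset_names,
                            substitute_position)

AC_PATTERN = "[RKS][YFW][DE][VIL]X{9}[KR]X{1,3}[DE]"
GC_PATTERN = "[RKS][YFW][CTGH][VIL]X{9}[KR]X{1,3}[DE]"
CORE_FUNC_PATTERN = "[RKS]X[DE]X{10}[KR]X{1,3}[DE]"


class TestResidueClass:
    def test_wildcard_has_empty_allowed(self):
        w = ResidueClass.wildcard()
        assert w.is_wildcard and not w.allowed

    def test_nonempty_required(self):
        with pytest.raises(ValueError):
            ResidueClass(frozenset(), False)

    def test_standard_codes_only(self):
        with pytest.raises(ValueError):
            ResidueClass.of("RB")  # B is an ambiguity code

    def test_matches(self):
        rc = ResidueClass.of("DE")
        assert rc.matches("D") and rc.matches("E") and not rc.matches("A")


class TestParse:
    def test_ac_core_shape(self):
        m = parse_motif(AC_PATTERN)
        assert len(m.elements) == 8
        assert m.min_span == 16
        assert m.max_span == 18

    def test_single_wildcard(self):
        m = parse_motif("X")
        assert len(m.elements) == 1
        assert m.min_span == m.max_span == 1
        assert m.elements[0].is_gap

    def test_functional_core_shape(self):
        m = parse_motif(CORE_FUNC_PATTERN)
        assert len(m.elements) == 7
        assert m.min_span == 16
        assert m.max_span == 18

    def test_bare_residue(self):
        m = parse_motif("RX{2}D")
        assert [str(e.residue_class) for e in m.elements] == ["[R]", "X", "[D]"]

    @pytest.mark.parametrize("bad", [
        "[RK", "[]", "X{3,1}", "[rk]", "[R]Z{2}" .replace("Z", "b"),
        "[RB]", "{2}", "X{a}", "X{1,2,3}", "[XR]", "X{0}",
    ])
    def test_parse_errors(self, bad):
        with pytest.raises(MotifParseError):
            parse_motif(bad)

    def test_error_reports_token_and_offset(self):
        with pytest.raises(MotifParseError) as exc:
            parse_motif("[RK]X{5,2}")
        assert exc.value.offset == 5
        assert "{5,2}" in exc.value.token

    def test_adjacent_gaps_merge(self):
        m = parse_motif("[R]XX{2}X{1,3}[D]")
        assert len(m.elements) == 3
        gap = m.elements[1]
        assert gap.min_repeat == 4 and gap.max_repeat == 6


class TestSerialize:
    def test_canonical_residue_order(self):
        assert motif_to_string(parse_motif("[SKR][WYF]")) == "[KRS][FWY]"

    def test_variable_gap_verbatim(self):
        assert motif_to_string(parse_motif("[R]X{1,3}[D]")) == "[R]X{1,3}[D]"

    def test_single_wildcard_no_braces(self):
        assert motif_to_string(parse_motif("[R]X{1}[D]")) == "[R]X[D]"

    def test_round_trip_core_pattern(self):
        m = parse_motif(AC_PATTERN, "m")
        again = parse_motif(motif_to_string(m), "m")
        assert again.elements == m.elements

    def test_dict_round_trip_presets(self):
        for name in preset_names():
            m = preset(name)
            assert Motif.from_dict(m.to_dict()) == m


class TestSubstitute:
    def test_gc_to_ac(self):
        gc = parse_motif(GC_PATTERN, "m")
        ac = substitute_position(gc, 2, ResidueClass.of("DE"))
        assert motif_to_string(ac) == motif_to_string(parse_motif(AC_PATTERN))

    def test_identity(self):
        ac = parse_motif(AC_PATTERN, "m")
        assert substitute_position(ac, 2, ResidueClass.of("DE")) == ac

    def test_involution(self):
        gc = parse_motif(GC_PATTERN, "m")
        there = substitute_position(gc, 2, ResidueClass.of("DE"))
        back = substitute_position(there, 2, ResidueClass.of("CTGH"))
        assert back == gc

    def test_gap_index_rejected(self):
        ac = parse_motif(AC_PATTERN, "m")
        with pytest.raises(ValueError):
            substitute_position(ac, 4, ResidueClass.of("DE"))

    def test_index_out_of_range(self):
        ac = parse_motif(AC_PATTERN, "m")
        with pytest.raises(IndexError):
            substitute_position(ac, 99, ResidueClass.of("DE"))

    def test_role_preserved(self):
        gc = preset("gc_core")
        ac = substitute_position(gc, 2, ResidueClass.of("DE"))
        assert ac.elements[2].role is Role.SUBSTRATE_SPECIFICITY


class TestConstrainWildcard:
    def test_fv_at_position5(self):
        ac = parse_motif(AC_PATTERN, "m")
        out = constrain_wildcard(ac, 5, ResidueClass.of("FV"))
        assert motif_to_string(out) == "[KRS][FWY][DE][ILV][FV]X{8}[KR]X{1,3}[DE]"
        assert out.min_span == ac.min_span
        assert out.max_span == ac.max_span

    def test_middle_of_gap_splits_three_ways(self):
        ac = parse_motif(AC_PATTERN, "m")
        out = constrain_wildcard(ac, 9, ResidueClass.of("G"))
        assert motif_to_string(out) == "[KRS][FWY][DE][ILV]X{4}[G]X{4}[KR]X{1,3}[DE]"

    def test_constrain_to_wildcard_is_identity(self):
        ac = parse_motif(AC_PATTERN, "m")
        assert constrain_wildcard(ac, 5, ResidueClass.wildcard()) == ac

    def test_position_on_class_element_rejected(self):
        ac = parse_motif(AC_PATTERN, "m")
        with pytest.raises(ValueError):
            constrain_wildcard(ac, 3, ResidueClass.of("G"))

    def test_variable_gap_rejected(self):
        ac = parse_motif(AC_PATTERN, "m")
        # position 15 sits in the X{1,3} gap of the minimal instantiation
        with pytest.raises(ValueError):
            constrain_wildcard(ac, 15, ResidueClass.of("G"))

    def test_position_outside_motif_rejected(self):
        ac = parse_motif(AC_PATTERN, "m")
        with pytest.raises(ValueError):
            constrain_wildcard(ac, 99, ResidueClass.of("G"))


class TestAnchor:
    def test_printed_anchor_pattern(self):
        ac = parse_motif(AC_PATTERN, "m")
        out = add_upstream_anchor(ac, ResidueClass.of("R"), 5, 20)
        assert motif_to_string(out) == \
            "[R]X{5,20}[KRS][FWY][DE][ILV]X{9}[KR]X{1,3}[DE]"
        assert out.elements[0].role is Role.ANCHOR

    def test_zero_gap_adjacent(self):
        ac = parse_motif(AC_PATTERN, "m")
        out = add_upstream_anchor(ac, ResidueClass.of("R"), 0, 0)
        assert motif_to_string(out).startswith("[R][KRS]")

    def test_negative_gap_rejected(self):
        ac = parse_motif(AC_PATTERN, "m")
        with pytest.raises(ValueError):
            add_upstream_anchor(ac, ResidueClass.of("R"), -1, 5)


class TestPresets:
    def test_all_six_present(self):
        assert preset_names() == ("gc_core", "ac_core", "ac_anchored",
                                  "ac_fv5", "ac_kr15", "functional_core")

    def test_kr15_printed_pattern(self):
        m = preset("ac_kr15")
        ref = parse_motif("[R]X{5,20}[RKS][YFW][DE][VIL]X{8}[KR][KR]X{0,2}[DE]")
        assert motif_to_string(m) == motif_to_string(ref)

    def test_ac_core_derivable_from_gc(self):
        gc = preset("gc_core")
        derived = substitute_position(gc, 2, ResidueClass.of("DE"))
        assert derived.elements == preset("ac_core").elements

    def test_anchored_derivable(self):
        derived = add_upstream_anchor(preset("ac_core"),
                                      ResidueClass.of("R"), 5, 20)
        assert derived.elements == preset("ac_anchored").elements

    def test_fv5_derivable(self):
        derived = constrain_wildcard(preset("ac_core"), 5,
                                     ResidueClass.of("FV"),
                                     Role.HYDROPHOBIC_POCKET)
        assert derived.elements == preset("ac_fv5").elements

    def test_unknown_name(self):
        with pytest.raises(KeyError) as exc:
            preset("nope")
        assert "gc_core" in str(exc.value)

    def test_transition_state_position_is_14(self):
        assert preset("ac_core").role_position(Role.TRANSITION_STATE) == 14

    def test_catalogue_round_trips(self):
        for entry in preset_catalogue():
            m = parse_motif(entry["pattern"], entry["name"])
            assert motif_to_string(m) == entry["pattern"]
            assert (m.min_span, m.max_span) == (entry["min_span"],
                                                entry["max_span"])


class TestInvariants:
    def test_span_accounting_after_operators(self):
        ac = preset("ac_core")
        for m in (substitute_position(ac, 0, ResidueClass.of("R")),
                  constrain_wildcard(ac, 7, ResidueClass.of("W")),
                  add_upstream_anchor(ac, ResidueClass.of("K"), 2, 4)):
            assert m.min_span == sum(e.min_repeat for e in m.elements)
            assert m.max_span == sum(e.max_repeat for e in m.elements)

    def test_duplicate_role_rejected(self):
        el = MotifElement(ResidueClass.of("R"), role=Role.ANCHOR)
        with pytest.raises(ValueError):
            Motif("m", (el, el))
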
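import pytest

from curlysmiles.annotation_model import (
    COMPONENT,
    Annotation,
    MarkerClass,
    classify_marker,
    parse_annotation,
    parse_dictionary,
    resolve_relative_pointer,
    serialize_dictionary,
)
from curlysmiles.errors import (
    AnnotationError,
    DictionaryError,
    PointerError,
    UnknownMarkerWarning,
)
from curlysmiles.smiles_graph import parse_plain_smiles

from conftest import FIGURE1


class TestClassification:
    @pytest.mark.parametrize("block,cls,marker", [
        ("R", MarkerClass.STEREO, "R"),
        ("Z", MarkerClass.STEREO, "Z"),
        ("-", MarkerClass.UNIT, "-"),
        ("~", MarkerClass.UNIT, "~"),
        ("-|sfn=SiO2", MarkerClass.GEAM, "-|"),
        ("-R", MarkerClass.GEAM, "-R"),
        ("-X", MarkerClass.GEAM, "-X"),
        ("=Y", MarkerClass.GEAM, "=Y"),
        ("~|", MarkerClass.GEAM, "~|"),
        (".|", MarkerClass.GEAM, ".|"),
        ("!re=+", MarkerClass.MDAM, "!r"),
        ("!a", MarkerClass.MDAM, "!a"),
        ("+rn=4", MarkerClass.OPAM, "+r"),
        ("+Rn=4-16", MarkerClass.OPAM, "+R"),
        ("+Lc=CC", MarkerClass.OPAM, "+L"),
        ("aq", MarkerClass.SSAM, "aq"),
        ("Mi", MarkerClass.MIAM, "Mi"),
    ])
    def test_marker_partition(self, block, cls, marker):
        got_cls, got_marker, _ = classify_marker(block)
        assert (got_cls, got_marker) == (cls, marker)

    @pytest.mark.parametrize("bad", ["", "?", "!z", "+q", "-Z", "=|", "1x"])
    def test_unknown_marker_shapes(self, bad):
        with pytest.raises(AnnotationError):
            classify_marker(bad)

    def test_unknown_registry_marker_warns_not_errors(self):
        with pytest.warns(UnknownMarkerWarning):
            cls, marker, _ = classify_marker("zz")
        assert cls is MarkerClass.SSAM

    def test_lone_stereodescriptor_has_no_entries(self):
        ann = parse_annotation("R")
        assert ann.marker_class is MarkerClass.STEREO and ann.entries == []

    def test_text_after_boundary_symbol_is_not_a_unit_annotation(self):
        # '-n=2' must not be read as boundary '-' plus a dictionary
        with pytest.raises(AnnotationError):
            parse_annotation("-n=2")


class TestAnchoring:
    def test_atom_context_rejects_component_classes(self):
        with pytest.raises(AnnotationError):
            parse_annotation("aq", context="atom")

    def test_component_context_rejects_atom_classes(self):
        with pytest.raises(AnnotationError):
            parse_annotation("-R", context="component")

    def test_end_context_resolves_by_class(self):
        assert parse_annotation("aq", context="end").anchor == COMPONENT
        assert parse_annotation("-R", context="end").anchor is None


class TestDictionary:
    def test_figure1_surface_entry(self):
        ann = parse_annotation("-|sfn=SiO2", context="atom")
        assert ann.marker == "-|"
        (e,) = ann.entries
        assert (e.key, e.value) == ("sfn", "SiO2")

    def test_ring_charge_entry(self):
        ann = parse_annotation("!re=+", context="atom")
        assert ann.marker == "!r"
        assert ann.entries[0].key == "e"
        assert ann.entries[0].parsed_value == +1

    def test_repeat_count_entry(self):
        ann = parse_annotation("+rn=4", context="atom")
        assert ann.entry("n").parsed_value == 4

    def test_integer_range_value(self):
        entries = parse_dictionary("n=4-16")
        assert entries[0].parsed_value == (4, 16)

    def test_recursive_ligand_value_keeps_internal_semicolons_and_braces(self):
        value = "CC(=O)COc1c{-}cc{-R}cc1C{+rn=4}"
        entries = parse_dictionary("c=" + value)
        assert entries[0].value == value
        sub = entries[0].parsed_value
        assert len(sub) == 1 and len(sub[0].body.atoms) == 12

    def test_empty_dictionary(self):
        assert parse_dictionary("") == []

    def test_customer_key_flagged_and_unvalidated(self):
        entries = parse_dictionary("$mykey=1")
        assert entries[0].customer and entries[0].parsed_value == 1

    @pytest.mark.parametrize("bad", ["novalue", "=1", "k=1;k=2", "1k=v"])
    def test_rejects(self, bad):
        with pytest.raises(DictionaryError):
            parse_dictionary(bad)

    def test_serialization_is_byte_identical(self):
        for text in ["sfn=SiO2", "n=4-16", "a=1;b=x;c=C{-}C",
                     "c=CC(=O)COc1c{-}cc{-R}cc1C{+rn=4}"]:
            assert serialize_dictionary(parse_dictionary(text)) == text


class TestRelativePointer:
    def test_figure1_pointer_resolves_to_surface_node(self):
        g = parse_plain_smiles(FIGURE1)
        ann = g.atoms[2].annotations[0]
        assert ann.entry("i").parsed_value == -2
        assert resolve_relative_pointer(ann, g) == 0
        target = g.atoms[0].annotations[0]
        assert target.entry("sfn").value == "SiO2"

    def test_positive_unit_offset(self):
        g = parse_plain_smiles("[Si]{-|i=+1}O{-|sfn=TiO2}")
        ann = g.atoms[0].annotations[0]
        assert resolve_relative_pointer(ann, g) == 1

    def test_out_of_range_offset(self):
        g = parse_plain_smiles("O{-|sfn=SiO2}C")
        ann = Annotation(MarkerClass.GEAM, "-|",
                         parse_dictionary("i=-5"), anchor=1)
        with pytest.raises(PointerError):
            resolve_relative_pointer(ann, g)

    def test_target_without_matching_annotation(self):
        from curlysmiles.smiles_graph import validate_pointers

        g = parse_plain_smiles("OC{-|i=-1}")  # O carries no -| annotation
        with pytest.raises(PointerError):
            validate_pointers(g)

    def test_planted_pointers_in_fuzzed_graphs_recover_target(self):
        from curlysmiles.fixtures import generate_notation
        from curlysmiles.notation import parse

        checked = 0
        for seed in range(120):
            text, truth = generate_notation(seed, "annotated")
            pn = parse(text)
            for anchor, offset, target in truth.components[0].pointers:
                g = pn[0].body
                ann = next(a for a in g.atoms[anchor].annotations
                           if a.entry("i") is not None)
                assert resolve_relative_pointer(ann, g) == target
                checked += 1
        assert checked >= 10
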
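import pytest

from curlysmiles.errors import (
    BondEndpointError,
    BranchError,
    RingClosureError,
    SqcError,
    StereoGlyphError,
    UnknownElementError,
)
from curlysmiles.smiles_graph import (
    MolecularGraph,
    parse_plain_smiles,
    parse_sqc,
    serialize_graph,
)

from conftest import FIGURE1


class TestParseSqc:
    @pytest.mark.parametrize("token,symbol,hcount,charge,isotope", [
        ("Co+2", "Co", 0, 2, None),
        ("*H2", "*", 2, 0, None),
        ("CH4", "C", 4, 0, None),
        ("O-", "O", 0, -1, None),
        ("N+", "N", 0, 1, None),
        ("Fe++", "Fe", 0, 2, None),
        ("13C", "C", 0, 0, 13),
        ("2H", "H", 0, 0, 2),
        ("nH", "N", 1, 0, None),
    ])
    def test_fields(self, token, symbol, hcount, charge, isotope):
        a = parse_sqc(token)
        assert (a.symbol, a.hcount, a.charge, a.isotope) == \
            (symbol, hcount, charge, isotope)

    @pytest.mark.parametrize("token,err", [
        ("", SqcError),
        ("Xx", UnknownElementError),
        ("C@H", StereoGlyphError),
        ("C+-", SqcError),
        ("q", UnknownElementError),
    ])
    def test_rejects(self, token, err):
        with pytest.raises(err):
            parse_sqc(token)


class TestParsePlainSmiles:
    def test_nitrate_graph(self):
        g = parse_plain_smiles("[O-]N(=O)=O")
        assert len(g.atoms) == 4 and len(g.bonds) == 3
        assert [b.symbol for b in g.bonds] == ["-", "=", "="]
        assert g.atoms[0].charge == -1 and g.atoms[1].charge == 0

    def test_wildcard_double_bond(self):
        g = parse_plain_smiles("[*H2]=[*]")
        assert [a.symbol for a in g.atoms] == ["*", "*"]
        assert g.atoms[0].hcount == 2
        (b,) = g.bonds
        assert b.symbol == "="

    def test_cyclopropane_ring_closure(self):
        g = parse_plain_smiles("C1CC1")
        assert len(g.atoms) == 3 and len(g.bonds) == 3
        assert sum(b.from_ring_closure for b in g.bonds) == 1

    def test_benzene_matches_hand_built_adjacency(self):
        # oracle: benzene is the 6-cycle with all-aromatic atoms and bonds
        g = parse_plain_smiles("c1ccccc1")
        assert all(a.aromatic for a in g.atoms)
        assert all(b.symbol == ":" for b in g.bonds)
        edges = {frozenset((b.a, b.b)) for b in g.bonds}
        assert edges == {frozenset((i, (i + 1) % 6)) for i in range(6)}

    def test_branches_change_neither_atom_nor_bond_count(self):
        linear = parse_plain_smiles("CCCO")
        branched = parse_plain_smiles("CC(C)O")
        assert len(linear.atoms) == len(branched.atoms)
        assert len(linear.bonds) == len(branched.bonds)

    def test_percent_ring_label(self):
        g = parse_plain_smiles("C%12CC%12")
        assert len(g.bonds) == 3

    @pytest.mark.parametrize("bad,err", [
        ("C@C", StereoGlyphError),
        ("C/C=C", StereoGlyphError),
        ("C\\C", StereoGlyphError),
        ("C~C", BondEndpointError),
        ("[C]$C", BondEndpointError),
        ("*C", BondEndpointError),
        ("C1CC", RingClosureError),
        ("C1CC2", RingClosureError),
        ("C(C", BranchError),
        ("C()C", BranchError),
        ("Zr", UnknownElementError),
    ])
    def test_rejects(self, bad, err):
        with pytest.raises(err):
            parse_plain_smiles(bad)

    def test_sqc_encoded_tilde_and_quadruple_accepted(self):
        g = parse_plain_smiles("[Si]~[Si]")
        assert g.bonds[0].symbol == "~"
        g = parse_plain_smiles("[Re]$[Re]")
        assert g.bonds[0].symbol == "$"

    def test_ring_bond_symbol_conflict(self):
        with pytest.raises(RingClosureError):
            parse_plain_smiles("C=1CC-1")
        # identical or one-sided symbols are fine
        assert parse_plain_smiles("C=1CC=1").bonds[-1].symbol == "="
        assert parse_plain_smiles("C=1CC1").bonds[-1].symbol == "="


class TestAnnotationAnchoring:
    def test_annotation_attaches_to_nearest_preceding_atom(self):
        g = parse_plain_smiles(FIGURE1)
        anchors = [(a.index, ann.marker)
                   for a in g.atoms for ann in a.annotations]
        assert (0, "-|") in anchors      # first surface oxygen
        assert (2, "-|") in anchors      # second surface oxygen
        assert anchors[-1][1] == "!r"    # ring-charge detail on closing atom

    def test_annotation_after_ring_digit_anchors_through_it(self):
        g = parse_plain_smiles("C1CC1{-R}")
        assert g.atoms[0].annotations == []
        assert g.atoms[2].annotations[0].marker == "-R"

    def test_component_annotation_goes_to_component(self):
        g = parse_plain_smiles("CC{aq}")
        assert g.component_annotations[0].marker == "aq"
        assert not any(a.annotations for a in g.atoms)


class TestRoundTrip:
    @pytest.mark.parametrize("text", [
        "[O-]N(=O)=O",
        "O{-|i=-2}",
        "C1CC1",
        "c1ccccc1",
        FIGURE1,
        "[Si]~[Si]",
        "C%12CC%12",
    ])
    def test_parse_serialize_is_byte_identical(self, text):
        assert serialize_graph(parse_plain_smiles(text)) == text

    def test_constructed_graph_round_trips_isomorphic(self):
        import networkx as nx

        g = parse_plain_smiles("CC(=O)C1CC1[O-]")
        g.tokens = None  # force the generic writer
        again = parse_plain_smiles(serialize_graph(g))

        def as_nx(mg):
            G = nx.Graph()
            for a in mg.atoms:
                G.add_node(a.index, symbol=a.symbol, charge=a.charge)
            for b in mg.bonds:
                G.add_edge(b.a, b.b, symbol=b.symbol)
            return G

        assert nx.is_isomorphic(
            as_nx(g), as_nx(again),
            node_match=lambda x, y: (x["symbol"], x["charge"])
            == (y["symbol"], y["charge"]),
            edge_match=lambda x, y: x["symbol"] == y["symbol"])
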
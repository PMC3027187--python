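import networkx as nx
import pytest

from curlysmiles.errors import NotationError, StrictStripError
from curlysmiles.notation import parse, serialize
from curlysmiles.sfn import compare_compositions, parse_sfn
from curlysmiles.smiles_graph import parse_plain_smiles, serialize_graph
from curlysmiles.transforms import (
    StripPolicy,
    expand_chain_repeat,
    expand_multipliers,
    expand_ring_repeat,
    molecular_formula,
    strip_annotations,
)

from conftest import (
    CALIX_UNIT,
    COBALT_NITRATE,
    COBALT_NITRATE_EXHAUSTIVE,
    FIGURE1,
    MEEP_UNIT,
)


def as_nx(g):
    G = nx.Graph()
    for a in g.atoms:
        G.add_node(a.index, symbol=a.symbol)
    for b in g.bonds:
        G.add_edge(b.a, b.b, symbol=b.symbol)
    return G


class TestExpandMultipliers:
    def test_cobalt_nitrate_hexahydrate_exhaustive_form(self):
        pn = expand_multipliers(parse(COBALT_NITRATE))
        assert serialize(pn) == COBALT_NITRATE_EXHAUSTIVE

    def test_identity_when_all_multipliers_one(self):
        pn = parse("CC.O")
        assert serialize(expand_multipliers(pn)) == "CC.O"

    def test_total_multiplicity_conserved_on_fuzzed_notations(self):
        from curlysmiles.fixtures import generate_notation

        for seed in range(80):
            text, truth = generate_notation(seed, "mixed")
            expanded = expand_multipliers(parse(text))
            assert len(expanded) == truth.total_multiplicity


class TestExpandRingRepeat:
    def test_calixarene_macrocycle(self):
        g = parse(CALIX_UNIT)[0].body
        ring = expand_ring_repeat(g)
        assert len(ring.atoms) == 4 * len(g.atoms)
        # joins are the final 4 bonds; removing them leaves 4 unit copies
        assert len(ring.bonds) == 4 * len(g.bonds) + 4

    def test_smallest_macrocycle(self):
        g = parse_plain_smiles("[Si]{-}[Ge]{+rn=2}")
        ring = expand_ring_repeat(g)
        assert len(ring.atoms) == 4
        assert len(ring.bonds) == 4  # 2 unit bonds + 2 joins

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_join_removal_yields_k_isomorphic_units(self, k):
        g = parse_plain_smiles("C{-}C(=O)N{+r}")
        unit_nx = as_nx(g)
        ring = expand_ring_repeat(g, k)
        assert len(ring.atoms) == k * len(g.atoms)
        joins = ring.bonds[-k:]
        G = as_nx(ring)
        G.remove_edges_from([(b.a, b.b) for b in joins])
        pieces = [G.subgraph(c) for c in nx.connected_components(G)]
        assert len(pieces) == k
        for piece in pieces:
            assert nx.is_isomorphic(
                piece, unit_nx,
                node_match=lambda x, y: x["symbol"] == y["symbol"])
        # the join edges close a single cycle through all copies
        H = nx.Graph([(b.a // len(g.atoms), b.b // len(g.atoms))
                      for b in joins])
        assert nx.is_connected(H) and H.number_of_nodes() == k

    def test_expanded_macrocycle_serializes_and_reparses(self):
        g = parse(CALIX_UNIT)[0].body
        ring = expand_ring_repeat(g)
        again = parse_plain_smiles(serialize_graph(ring))
        assert len(again.atoms) == len(ring.atoms)
        assert len(again.bonds) == len(ring.bonds)

    @pytest.mark.parametrize("bad,msg", [
        ("C{-}C", "\\+r"),
        ("C{+rn=4}", "boundary"),
        ("C{-}C{+rn=1}", "at least 2"),
        ("C{-}C{-}C{+rn=3}", "more than one boundary"),
    ])
    def test_rejects(self, bad, msg):
        with pytest.raises(NotationError, match=msg):
            expand_ring_repeat(parse_plain_smiles(bad))


class TestExpandChainRepeat:
    def test_meep_chain_of_three(self):
        g = parse_plain_smiles(MEEP_UNIT)
        chain = expand_chain_repeat(g, 3)
        assert len(chain.atoms) == 3 * len(g.atoms)
        assert len(chain.bonds) == 3 * len(g.bonds) + 2

    def test_k_equal_one_is_the_unit_itself(self):
        g = parse_plain_smiles(MEEP_UNIT)
        chain = expand_chain_repeat(g, 1)
        assert len(chain.atoms) == len(g.atoms)
        assert len(chain.bonds) == len(g.bonds)

    def test_terminal_bonds_stay_dangling(self):
        from curlysmiles.annotation_model import MarkerClass

        chain = expand_chain_repeat(parse_plain_smiles(MEEP_UNIT), 2)
        units = [a for at in chain.atoms for a in at.annotations
                 if a.marker_class is MarkerClass.UNIT]
        assert len(units) == 2  # one open bond at each chain end

    def test_open_ended_unit_requires_caller_count(self):
        g = parse_plain_smiles(MEEP_UNIT)
        with pytest.raises(NotationError, match="open-ended"):
            expand_chain_repeat(g)

    def test_atom_count_scales_on_fuzzed_units(self):
        for k in (1, 2, 4):
            g = parse_plain_smiles("C{-}CO[Si]{+n}")
            chain = expand_chain_repeat(g, k)
            assert len(chain.atoms) == k * 4


class TestStripAnnotations:
    def test_drop_yields_plain_skeleton(self):
        out = strip_annotations(parse(FIGURE1), StripPolicy.DROP)
        assert out == "O[Si](O)(O)CCCn1ccnc1"
        # output re-parses as plain SMILES with zero annotations
        g = parse_plain_smiles(out)
        assert not g.all_annotations()

    def test_plain_input_is_a_noop(self):
        assert strip_annotations(parse("CCO")) == "CCO"

    def test_strict_refuses_group_vs_radical(self):
        # the methyl group C{-} must not silently become the radical [CH3]
        with pytest.raises(StrictStripError, match="{-}"):
            strip_annotations(parse("C{-}"), StripPolicy.STRICT)

    def test_strict_passes_stereodescriptors(self):
        assert strip_annotations(parse("C{R}(N)O"),
                                 StripPolicy.STRICT) == "C(N)O"

    def test_multipliers_expand_to_exhaustive_plain_form(self):
        assert strip_annotations(parse("O{2}")) == "O.O"

    def test_special_forms_have_no_plain_reading(self):
        with pytest.raises(NotationError):
            strip_annotations(parse("{*SiO2}"))


class TestMolecularFormula:
    def test_nitrate_matches_hand_count(self):
        comp = molecular_formula(parse_plain_smiles("[O-]N(=O)=O"))
        assert comp.flattened == {"O": 3, "N": 1}
        assert comp.charge == -1

    def test_water_implicit_hydrogens(self):
        comp = molecular_formula(parse_plain_smiles("O"))
        assert comp.flattened == {"O": 1, "H": 2}
        assert comp.charge == 0

    def test_methyl_radical(self):
        comp = molecular_formula(parse_plain_smiles("[CH3]"))
        assert comp.flattened == {"C": 1, "H": 3}

    def test_graph_formula_comparable_to_written_sfn(self):
        graph_comp = molecular_formula(parse_plain_smiles("[O-]N(=O)=O"))
        assert compare_compositions(graph_comp, parse_sfn("NO3(1-)"))

    def test_wildcard_formula_undefined(self):
        with pytest.raises(NotationError, match="wildcard"):
            molecular_formula(parse_plain_smiles("[*H2]=[*]"))

    def test_benzene_aromatic_hydrogens(self):
        comp = molecular_formula(parse_plain_smiles("c1ccccc1"))
        assert comp.flattened == {"C": 6, "H": 6}
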
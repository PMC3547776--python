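"""Ontology model, OBO dialect round-trip, ancestry and Rule-4 composites."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoclass.errors import (DefinitionError, OboParseError,
                              UnknownTermError)
from ontoclass.logic import compile_definition
from ontoclass.ontology import (ChemOntology, ClassNode, parse_obo,
                                serialize_obo)

from conftest import mol

MINI_OBO = """\
format-version: 1.2
ontology: mini

[Term]
id: T:1
name: root

[Term]
id: T:2
name: ring compounds
synonym: "ringförmige Verbindungen" EXACT []
oc_smarts: [R]
is_a: T:1

[Term]
id: T:3
name: carbocycles
oc_smarts: [#6R]@[#6R]
oc_smarts: ![!#6;!#1]
is_a: T:2
"""


def small_dag(draw_edges):
    """Build a ChemOntology from explicit (child, parent) int pairs."""
    ids = sorted({x for e in draw_edges for x in e})
    ont = ChemOntology()
    for i in ids:
        ont.add_node(ClassNode(id=f"N:{i}", name=f"node {i}"))
    for child, parent in draw_edges:
        ont.add_edge(f"N:{child}", f"N:{parent}")
    return ont


class TestParse:
    def test_units_and_forbidden_prefix(self):
        ont = parse_obo(io.StringIO(MINI_OBO))
        node = ont.nodes["T:3"]
        assert len(node.definition.allowed) == 1
        assert len(node.definition.forbidden) == 1
        assert node.definition.forbidden[0].patterns == ("[!#6;!#1]",)

    def test_stanza_without_structure_tags_is_abstract(self):
        ont = parse_obo(io.StringIO(MINI_OBO))
        assert ont.nodes["T:1"].definition is None
        assert ont.nodes["T:1"].is_abstract

    def test_duplicate_id_is_an_error(self):
        text = MINI_OBO + "\n[Term]\nid: T:1\nname: again\n"
        with pytest.raises(OboParseError, match="duplicate"):
            parse_obo(io.StringIO(text))

    def test_dangling_is_a_lists_the_missing_id(self):
        text = MINI_OBO + "\n[Term]\nid: T:4\nis_a: T:99\n"
        with pytest.raises(OboParseError, match="T:99"):
            parse_obo(io.StringIO(text))

    def test_invalid_smarts_names_term_and_line(self):
        text = MINI_OBO + "\n[Term]\nid: T:4\noc_smarts: [[nope\n"
        with pytest.raises(DefinitionError) as exc:
            parse_obo(io.StringIO(text))
        assert "T:4" in str(exc.value)

    def test_both_definition_kinds_rejected(self):
        text = (MINI_OBO
                + "\n[Term]\nid: T:4\noc_smarts: [R]\noc_smiles: CCO\n")
        with pytest.raises(OboParseError, match="both"):
            parse_obo(io.StringIO(text))

    def test_is_a_comment_stripped(self):
        ont = parse_obo(io.StringIO(
            MINI_OBO + "\n[Term]\nid: T:4\nis_a: T:1 ! root\n"))
        assert ont.nodes["T:4"].parents == ["T:1"]

    def test_unknown_tags_preserved(self):
        ont = parse_obo(io.StringIO(
            MINI_OBO + "\n[Term]\nid: T:4\nxref: CAS:64-17-5\n"))
        assert ("xref", "CAS:64-17-5") in ont.nodes["T:4"].annotations
        assert "xref: CAS:64-17-5" in serialize_obo(ont)


class TestRoundTrip:
    def test_fixture_round_trip_identity(self, ont_a, ont_b):
        for ont in (ont_a, ont_b):
            text = serialize_obo(ont)
            again = parse_obo(io.StringIO(text))
            assert again == ont
            assert serialize_obo(again) == text

    def test_unicode_synonyms_survive(self):
        ont = parse_obo(io.StringIO(MINI_OBO))
        assert ont.nodes["T:2"].synonyms == ["ringförmige Verbindungen"]
        again = parse_obo(io.StringIO(serialize_obo(ont)))
        assert again.nodes["T:2"].synonyms == ["ringförmige Verbindungen"]

    def test_empty_ontology_serializes_to_header_only(self):
        text = serialize_obo(ChemOntology())
        assert text.strip() == "format-version: 1.2"
        assert len(parse_obo(io.StringIO(text))) == 0

    def test_obonet_agrees_on_structure(self, ont_a, tmp_path):
        # independent OBO reader as cross-check oracle
        obonet = pytest.importorskip("obonet")
        path = tmp_path / "a.obo"
        path.write_text(serialize_obo(ont_a))
        g = obonet.read_obo(path, ignore_obsolete=False)
        assert set(g.nodes) == set(ont_a.nodes)
        ours = {(c, p) for c in ont_a.nodes
                for p in ont_a.nodes[c].parents}
        theirs = {(c, p) for c, p, k in g.edges(keys=True) if k == "is_a"}
        assert ours == theirs


class TestAncestry:
    def test_leaf_ancestors_follow_every_path(self, ont_b):
        from ontoclass.fixtures import B
        got = ont_b.ancestors(B["5β-androstanes"])
        assert got == {B["androstanes"], B["steroids"]}

    def test_root_has_no_ancestors(self, ont_a):
        assert ont_a.ancestors("OCA:0000001") == set()

    def test_diamond_reports_each_ancestor_once(self):
        ont = small_dag([(3, 1), (3, 2), (1, 0), (2, 0)])
        assert ont.ancestors("N:3") == {"N:1", "N:2", "N:0"}

    def test_unknown_id_raises(self, ont_a):
        with pytest.raises(UnknownTermError):
            ont_a.ancestors("OCA:9999999")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 49), st.integers(0, 49)).filter(
            lambda e: e[0] < e[1]),  # child < parent index: acyclic
        min_size=1, max_size=120))
    def test_matches_brute_force_transitive_closure(self, edges):
        ont = small_dag(edges)
        adj = {}
        for c, p in edges:
            adj.setdefault(f"N:{c}", set()).add(f"N:{p}")
        for node in ont.nodes:
            # plain iterative reachability, no graph library
            seen, stack = set(), list(adj.get(node, ()))
            while stack:
                x = stack.pop()
                if x not in seen:
                    seen.add(x)
                    stack.extend(adj.get(x, ()))
            assert ont.ancestors(node) == seen


class TestEffectiveDefinition:
    def test_child_must_satisfy_parent_too(self):
        # an ether-like pattern under cycloalkanes: tetrahydropyran has
        # the ether oxygen but its ring heteroatom breaks the parent
        ont = ChemOntology()
        ont.add_node(ClassNode(
            id="X:1", name="cycloalkanes",
            definition=compile_definition(
                ["[#6R]@[#6R]"],
                ["[#6R]:[#6R]", "[#6R]#[#6R]", "[#6R]=[#6R]", "[!#6;!#1]"])))
        ont.add_node(ClassNode(
            id="X:2", name="ring ethers",
            definition=compile_definition(["[OX2]([#6])[#6]"], []),
            parents=["X:1"]))
        composite = ont.effective_definition("X:2")
        assert not composite.satisfied_by(mol("C1CCOCC1"))
        assert composite.explain(mol("C1CCOCC1"))["X:2"].matched
        assert not composite.explain(mol("C1CCOCC1"))["X:1"].matched

    def test_abstract_ancestors_impose_nothing(self, ont_a):
        from ontoclass.fixtures import A
        composite = ont_a.effective_definition(A["carbon compounds"])
        assert [t for t, _ in composite.members] == [A["carbon compounds"]]
        assert composite.satisfied_by(mol("C"))

    def test_fully_abstract_chain_satisfied_by_nothing(self):
        ont = small_dag([(1, 0)])
        assert not ont.effective_definition("N:1").satisfied_by(mol("C"))

    def test_order_independent_over_probe_pool(self, ont_a, pool_a):
        # evaluating members in any traversal order yields the same
        # satisfaction set over the probe pool
        import random

        from ontoclass.fixtures import A
        from ontoclass.logic import evaluate_class

        composite = ont_a.effective_definition(A["dialkyl ethers"])
        rng = random.Random(11)
        for lm in pool_a[::5]:
            m = mol(lm.smiles)
            want = composite.satisfied_by(m)
            members = list(composite.members)
            rng.shuffle(members)
            got = all(evaluate_class(m, d).matched for _, d in members)
            assert got == want
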
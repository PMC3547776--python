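"""Boolean SMARTS class-definition logic."""

import random

import pytest
from rdkit import Chem

from ontoclass.errors import DefinitionError
from ontoclass.logic import (CompoundDefinition, MatchUnit,
                             compile_definition, evaluate_class,
                             evaluate_compound, parse_logic_lines)

from conftest import (ORACLE_SMILES, brute_force_satisfies, mol,
                      random_definition_lines)

CYCLOALKANE = compile_definition(
    ["[#6R]@[#6R]"],
    ["[#6R]:[#6R]", "[#6R]#[#6R]", "[#6R]=[#6R]", "[!#6;!#1]"],
)
PRIMARY_AMINE = compile_definition(["[N;H2v3][#6;!$(C=[O,S,N,P])]"], [])


class TestCompile:
    def test_cycloalkane_unit_structure(self):
        assert len(CYCLOALKANE.allowed) == 1
        assert len(CYCLOALKANE.forbidden) == 4
        assert CYCLOALKANE.allowed[0].patterns == ("[#6R]@[#6R]",)

    def test_invalid_smarts_raises_definition_error(self):
        with pytest.raises(DefinitionError) as exc:
            compile_definition(["[#6R]@[#6R]", "[[bogus"], [], term="broken")
        assert "broken" in str(exc.value)
        assert "[[bogus" in str(exc.value)

    def test_and_separator_builds_multi_pattern_unit(self):
        # note the SMARTS neighbor-order subtlety: the implicit H of a
        # leading chiral atom shifts parity, so the stereo pattern is
        # written in the same atom order as the molecule SMILES
        d = compile_definition(
            ["C[C@@H](O)C(O)=O & [CX4]([CH3])([OX2H])"], [])
        assert len(d.allowed) == 1
        assert d.allowed[0].patterns == (
            "C[C@@H](O)C(O)=O", "[CX4]([CH3])([OX2H])")
        # both patterns must hit (R)-lactic acid
        assert evaluate_class(mol("C[C@@H](O)C(O)=O"), d).matched
        # the stereo pattern rules out the (S) enantiomer
        assert not evaluate_class(mol("C[C@H](O)C(O)=O"), d).matched

    def test_empty_definition_is_abstract(self):
        d = compile_definition([], [])
        assert d.is_abstract
        for smi in ("C", "CCO", "c1ccccc1"):
            assert not evaluate_class(mol(smi), d).matched

    def test_forbidden_prefix_split(self):
        allowed, forbidden = parse_logic_lines(
            ["[#6R]@[#6R]", "![#6R]:[#6R]", "! [#6R]=[#6R]"])
        assert allowed == ["[#6R]@[#6R]"]
        assert forbidden == ["[#6R]:[#6R]", "[#6R]=[#6R]"]

    def test_unit_requires_a_pattern(self):
        with pytest.raises(DefinitionError):
            MatchUnit(())


class TestEvaluateClass:
    @pytest.mark.parametrize("smiles,expected", [
        ("C1CCCCC1", True),      # cyclohexane: saturated carbocycle
        ("c1ccccc1", False),     # benzene: aromatic ring bonds
        ("C1=CCCCC1", False),    # cyclohexene: ring double bond
        ("ClC1CCCCC1", False),   # chlorocyclohexane: heteroatom
        ("CC1CCCCC1", True),
        ("CCCC", False),         # no ring at all
    ])
    def test_cycloalkane_examples(self, smiles, expected):
        assert evaluate_class(mol(smiles), CYCLOALKANE).matched is expected

    def test_benzene_violating_unit_is_the_aromatic_pattern(self):
        res = evaluate_class(mol("c1ccccc1"), CYCLOALKANE)
        assert not res.matched
        assert res.violating_forbidden_unit == 0  # [#6R]:[#6R]

    @pytest.mark.parametrize("smiles,expected", [
        ("CCN", True),           # ethylamine
        ("CC(N)=O", False),      # acetamide: N on carbonyl carbon
        ("CN(C)C", False),       # tertiary amine: no NH2
        ("Nc1ccccc1", True),     # aniline
    ])
    def test_primary_amine_examples(self, smiles, expected):
        assert evaluate_class(mol(smiles), PRIMARY_AMINE).matched is expected

    def test_match_result_embeddings_cover_reported_unit(self):
        res = evaluate_class(mol("C1CCCCC1"), CYCLOALKANE)
        assert res.matched
        assert res.triggering_allowed_unit == 0
        assert res.violating_forbidden_unit is None
        assert len(res.atom_embeddings) == 1  # one pattern in the unit
        assert res.atom_embeddings[0], "at least one embedding reported"
        for emb in res.atom_embeddings[0]:
            assert len(emb) == 2  # two ring atoms per embedding

    def test_explicit_hydrogen_pattern_matches(self):
        # hydrogen-complete patterns are evaluated on an H-explicit copy
        d = compile_definition(["[H]OC([H])([H])"], [])
        assert evaluate_class(mol("CO"), d).matched
        assert not evaluate_class(mol("C"), d).matched


class TestOracleEquivalence:
    def test_randomized_pairs_match_brute_force(self):
        rng = random.Random(20240917)
        mols = {s: mol(s) for s in ORACLE_SMILES}
        for _ in range(1000):
            allowed, forbidden = random_definition_lines(rng)
            smiles = rng.choice(ORACLE_SMILES)
            d = compile_definition(allowed, forbidden)
            got = evaluate_class(mols[smiles], d).matched
            want = brute_force_satisfies(
                mols[smiles],
                [u.patterns for u in d.allowed],
                [u.patterns for u in d.forbidden],
            )
            assert got == want, (smiles, allowed, forbidden)

    def test_monotonicity_of_unit_sets(self):
        rng = random.Random(4)
        for _ in range(200):
            allowed, forbidden = random_definition_lines(rng)
            smiles = rng.choice(ORACLE_SMILES)
            m = mol(smiles)
            base = evaluate_class(m, compile_definition(allowed, forbidden))
            extra = rng.choice(
                ["[#6]", "[#8]", "[R]", "[CX4]", "[!#6;!#1]"])
            # adding a forbidden unit never turns a non-match into a match
            more_forbidden = compile_definition(allowed, forbidden + [extra])
            if not base.matched:
                assert not evaluate_class(m, more_forbidden).matched
            # adding an allowed unit never turns a match into a non-match
            more_allowed = compile_definition(allowed + [extra], forbidden)
            if base.matched:
                assert evaluate_class(m, more_allowed).matched

    def test_failing_all_allowed_units_rejects_regardless_of_forbidden(self):
        # De Morgan sanity: no allowed hit -> rejected, forbidden irrelevant
        d_with = compile_definition(["[#7]"], ["[#6]"])
        d_without = compile_definition(["[#7]"], [])
        m = mol("CCO")  # no nitrogen
        assert not evaluate_class(m, d_with).matched
        assert not evaluate_class(m, d_without).matched


class TestCompoundDefinition:
    GLUCOSE = (
        "[H]OC([H])([H])[C@@]([H])(O[H])[C@@]1([H])OC([H])(O[H])"
        "[C@]([H])(O[H])[C@@]1([H])O[H]",
        "[H]OC([H])([H])[C@@]1([H])OC([H])(O[H])[C@]([H])(O[H])"
        "[C@@]([H])(O[H])[C@]1([H])O[H]",
        "[H]OC([H])([H])[C@@]([H])(O[H])[C@@]([H])(O[H])[C@]([H])(O[H])"
        "[C@@]([H])(O[H])C([H])=O",
    )

    def test_each_printed_glucose_form_matches_the_or_set(self):
        d = CompoundDefinition(self.GLUCOSE)
        for rep in self.GLUCOSE:
            assert evaluate_compound(Chem.MolFromSmiles(rep), d)

    def test_enantiomer_of_every_centre_does_not_match(self):
        d = CompoundDefinition(self.GLUCOSE)
        l_glucose = (self.GLUCOSE[2]
                     .replace("[C@@]", "[X]").replace("[C@]", "[C@@]")
                     .replace("[X]", "[C@]"))
        assert not evaluate_compound(Chem.MolFromSmiles(l_glucose), d)

    def test_lactic_acid_enantiomers_are_distinct(self):
        r_class = CompoundDefinition(("C[C@@H](O)C(O)=O",))
        assert evaluate_compound(Chem.MolFromSmiles("C[C@@H](O)C(O)=O"), r_class)
        assert not evaluate_compound(Chem.MolFromSmiles("C[C@H](O)C(O)=O"), r_class)

    def test_representation_must_parse(self):
        with pytest.raises(DefinitionError):
            CompoundDefinition(("not-a-smiles",))
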
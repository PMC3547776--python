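import pytest
from rdkit import Chem, RDLogger

from ontoclass.chem import normalize
from ontoclass.fixtures import (build_ontology_A, build_ontology_B,
                                labeled_pool, steroid_probes)

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def ont_a():
    return build_ontology_A()


@pytest.fixture(scope="session")
def ont_b():
    return build_ontology_B()


@pytest.fixture(scope="session")
def pool_a(ont_a):
    return labeled_pool(ont_a)


@pytest.fixture(scope="session")
def probes_b(ont_b):
    return steroid_probes(ont_b)


def mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, f"fixture SMILES must parse: {smiles!r}"
    return normalize(m)


# shared random-pool material for oracle tests -------------------------------

ORACLE_SMARTS = [
    "[#6]", "[#8]", "[#7]", "[R]", "[a]", "[!#6;!#1]", "[CX4]", "[OX2H]",
    "[NX3]", "[#6R]@[#6R]", "[#6R]:[#6R]", "[#6R]=[#6R]", "[CX3]=[OX1]",
    "[F,Cl,Br,I]", "[#6]=[#6]", "[#6]#[#7]", "[OX2]([#6])[#6]", "[nX3H]",
    "[CH3]", "[N;H2v3][#6]",
]

ORACLE_SMILES = [
    "C", "CC", "CCO", "CCN", "c1ccccc1", "C1CCCCC1", "C1=CCCCC1", "CC(N)=O",
    "CC(=O)O", "CCOCC", "COc1ccccc1", "Oc1ccccc1", "CCCl", "c1cnc[nH]1",
    "CC#N", "C=C", "CC(C)O", "C1CCOC1", "NCC(=O)O", "O", "[Na+].[Cl-]",
    "CC(=O)Cl", "COC(C)=O", "c1ccoc1", "CN(C)C", "OC(=O)c1ccccc1",
    "ClC1CCCCC1", "OCCOCCCl", "CCc1ncc[nH]1", "C1CCC2CCCCC2C1",
]


def brute_force_satisfies(molecule: Chem.Mol, allowed, forbidden) -> bool:
    """Independent boolean-formula oracle.

    Tests every SMARTS individually (fresh compilation, no shared code
    with the package evaluator) and applies the formula explicitly:
    (OR over allowed unit conjunctions) AND NOT (OR over forbidden).
    """

    def pattern_hits(pattern: str) -> bool:
        q = Chem.MolFromSmarts(pattern)
        assert q is not None
        target = molecule
        if "[H" in pattern or "#1" in pattern:
            target = Chem.AddHs(molecule)
        return target.HasSubstructMatch(q, useChirality=True)

    def unit_hits(patterns) -> bool:
        return all(pattern_hits(p) for p in patterns)

    if not allowed:
        return False
    if not any(unit_hits(u) for u in allowed):
        return False
    return not any(unit_hits(u) for u in forbidden)


def random_definition_lines(rng):
    """Random (allowed_lines, forbidden_lines) over the oracle SMARTS pool."""
    def unit():
        k = rng.choice([1, 1, 1, 2])
        return " & ".join(rng.choice(ORACLE_SMARTS) for _ in range(k))

    n_allowed = rng.choice([1, 1, 2, 3])
    n_forbidden = rng.choice([0, 1, 1, 2])
    return ([unit() for _ in range(n_allowed)],
            [unit() for _ in range(n_forbidden)])
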
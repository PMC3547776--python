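"""Desk-scale fixture ontologies and a labeled synthetic molecule generator.

Two small ontologies exercise every mechanism of the class-definition
logic without external downloads:

* **Ontology A** — functional groups: an ether subtree (dialkyl /
  alkyl-aryl / diaryl), primary amines, cycloalkanes with the full
  allowed/forbidden logic, narrow vs broad carboxylic-acid classes, an
  imidazole class restricted to single-ring membership (so the fused
  benzimidazole stays out), and exact-compound nodes for the lactic
  acid stereoisomer family and the three ring/chain forms of D-glucose.
* **Ontology B** — steroid expert knowledge: androstanes and pregnanes
  as *sibling* classes. A pregnane contains the androstane skeleton as
  a substructure, so the androstane classes carry forbidden units that
  exclude any carbon substituent at C-17 — single-bonded and
  double-bonded — which is what keeps pregnanes out. The 5α/5β
  subclasses pair a stereochemistry pattern with an atom-list pattern
  in one AND unit, because SMARTS atom lists would break R/S priority
  assignment if both constraints lived in a single expression.

The steroid scaffold SMILES are authored, not copied: ring- and
atom-count assertions (four fused rings, 19 carbons for androstane, 21
for pregnane) plus a one-off 3D ring-fusion analysis fixed which C-5
epimer is labelled 5α (trans A/B fusion) and which 5β (cis).

The labeled generator emits molecules with ground-truth class labels
(ancestor-closed against ontology A) plus decoys that each just-miss a
class for one recorded reason — an aromatic ring posing as a
cycloalkane, an amide posing as an amine, an ester oxygen posing as an
ether.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .logic import CompoundDefinition, compile_definition
from .ontology import ChemOntology, ClassNode, serialize_obo

# ---------------------------------------------------------------------------
# Ontology A — functional groups

A = {
    "compounds": "OCA:0000001",
    "carbon compounds": "OCA:0000002",
    "cyclic compounds": "OCA:0000003",
    "hetero compounds": "OCA:0000004",
    "aromatic compounds": "OCA:0000005",
    "cycloalkanes": "OCA:0000006",
    "amines": "OCA:0000007",
    "primary amines": "OCA:0000008",
    "ethers": "OCA:0000009",
    "dialkyl ethers": "OCA:0000010",
    "alkyl aryl ethers": "OCA:0000011",
    "diaryl ethers": "OCA:0000012",
    "alcohols": "OCA:0000013",
    "carboxylic acids": "OCA:0000014",
    "carboxylic acid derivatives": "OCA:0000015",
    "organohalogen compounds": "OCA:0000016",
    "imidazoles": "OCA:0000017",
    "lactic acid": "OCA:0000018",
    "(R)-lactic acid": "OCA:0000019",
    "(S)-lactic acid": "OCA:0000020",
    "rac-lactic acid": "OCA:0000021",
    "D-glucose": "OCA:0000022",
}

#: the three printed connection tables of D-glucose: pyranose, furanose
#: and open-chain form (C-1 stereochemistry deliberately undefined)
GLUCOSE_REPRESENTATIONS = (
    "[H]OC([H])([H])[C@@]([H])(O[H])[C@@]1([H])OC([H])(O[H])[C@]([H])(O[H])[C@@]1([H])O[H]",
    "[H]OC([H])([H])[C@@]1([H])OC([H])(O[H])[C@]([H])(O[H])[C@@]([H])(O[H])[C@]1([H])O[H]",
    "[H]OC([H])([H])[C@@]([H])(O[H])[C@@]([H])(O[H])[C@]([H])(O[H])[C@@]([H])(O[H])C([H])=O",
)

R_LACTIC = "C[C@@H](O)C(O)=O"
S_LACTIC = "C[C@H](O)C(O)=O"
RAC_LACTIC = "C[C@@H](O)C(O)=O.C[C@H](O)C(O)=O"
FLAT_LACTIC = "CC(O)C(=O)O"

#: cycloalkane class logic: a carbon-carbon ring bond, and neither
#: aromatic / triple / double ring bonds nor any non-carbon heavy atom
CYCLOALKANE_ALLOWED = ["[#6R]@[#6R]"]
CYCLOALKANE_FORBIDDEN = ["[#6R]:[#6R]", "[#6R]#[#6R]", "[#6R]=[#6R]",
                         "[!#6;!#1]"]

#: a three-valent nitrogen with two hydrogens bound to a carbon that is
#: not double-bonded to O, S, N or P
PRIMARY_AMINE_SMARTS = "[N;H2v3][#6;!$(C=[O,S,N,P])]"

_A_CLASS_NODES = [
    # (name, parents, allowed, forbidden, scope, synonyms)
    ("compounds", [], [], [], "narrow", ["chemical compounds"]),
    ("carbon compounds", ["compounds"], ["[#6]"], [], "narrow", []),
    ("cyclic compounds", ["compounds"], ["[R]"], [], "narrow", []),
    ("hetero compounds", ["compounds"], ["[!#6;!#1]"], [], "narrow", []),
    ("aromatic compounds", ["cyclic compounds"], ["[a]"], [], "narrow", []),
    ("cycloalkanes", ["carbon compounds", "cyclic compounds"],
     CYCLOALKANE_ALLOWED, CYCLOALKANE_FORBIDDEN, "narrow",
     ["cyclo-alkanes"]),
    ("amines", ["carbon compounds", "hetero compounds"],
     ["[NX3;$([NX3][#6]);!$([NX3]C=[O,S,N,P]);!$([NX3]~[!#6;!#1])]"],
     [], "narrow", []),
    ("primary amines", ["amines"], [PRIMARY_AMINE_SMARTS], [], "narrow", []),
    ("ethers", ["carbon compounds", "hetero compounds"],
     ["[O;X2;!a]([#6;!$([#6]=[O,S,N])])[#6;!$([#6]=[O,S,N])]"],
     [], "narrow", []),
    ("dialkyl ethers", ["ethers"], ["[O;X2;!a]([CX4])[CX4]"], [], "narrow", []),
    ("alkyl aryl ethers", ["ethers", "aromatic compounds"],
     ["[O;X2]([CX4])[c]"], [], "narrow", []),
    ("diaryl ethers", ["ethers", "aromatic compounds"],
     ["[O;X2]([c])[c]"], [], "narrow", []),
    ("alcohols", ["carbon compounds", "hetero compounds"],
     ["[OX2H][CX4]"], [], "narrow", []),
    ("carboxylic acids", ["carbon compounds", "hetero compounds"],
     ["[CX3](=O)[OX2H1]"], [], "narrow", []),
    ("carboxylic acid derivatives", ["carbon compounds", "hetero compounds"],
     ["[CX3](=O)[OX2H0,NX3,F,Cl,Br,I]"], [], "broad", []),
    ("organohalogen compounds", ["carbon compounds", "hetero compounds"],
     ["[#6][F,Cl,Br,I]"], [], "narrow", []),
    # each ring atom restricted to exactly one ring, so fused systems
    # (benzimidazole) are a distinct class, not substituted imidazoles
    ("imidazoles", ["aromatic compounds", "hetero compounds",
                    "carbon compounds"],
     ["[cR1]1[cR1][nR1H0][cR1][nR1H]1"], [], "narrow", []),
]

_A_COMPOUND_NODES = [
    # (name, parents, representations, synonyms)
    ("lactic acid", ["carboxylic acids", "alcohols"], (FLAT_LACTIC,),
     ["2-hydroxy-propanoic acid"]),
    ("(R)-lactic acid", ["lactic acid"], (R_LACTIC,), ["D-(−)-lactic acid"]),
    ("(S)-lactic acid", ["lactic acid"], (S_LACTIC,), ["L-(+)-lactic acid"]),
    ("rac-lactic acid", ["lactic acid"], (RAC_LACTIC,), []),
    ("D-glucose", ["alcohols"], GLUCOSE_REPRESENTATIONS, ["dextrose"]),
]


def build_ontology_A() -> ChemOntology:
    """Functional-group fixture ontology (ethers, amines, cycloalkanes...)."""
    ont = ChemOntology(header=[("format-version", "1.2"),
                               ("ontology", "ontoclass-fixture-A")])
    for name, parents, allowed, forbidden, scope, synonyms in _A_CLASS_NODES:
        definition = (compile_definition(allowed, forbidden, term=A[name])
                      if allowed or forbidden else None)
        ont.add_node(ClassNode(id=A[name], name=name, synonyms=list(synonyms),
                               definition=definition, scope=scope))
    for name, parents, reps, synonyms in _A_COMPOUND_NODES:
        ont.add_node(ClassNode(id=A[name], name=name, synonyms=list(synonyms),
                               definition=CompoundDefinition(reps, term=A[name])))
    for name, parents, *_ in _A_CLASS_NODES:
        for p in parents:
            ont.add_edge(A[name], A[p])
    for name, parents, _, _ in _A_COMPOUND_NODES:
        for p in parents:
            ont.add_edge(A[name], A[p])
    return ont


# ---------------------------------------------------------------------------
# Ontology B — androstanes and pregnanes

B = {
    "steroids": "OCB:0000001",
    "androstanes": "OCB:0000002",
    "5α-androstanes": "OCB:0000003",
    "5β-androstanes": "OCB:0000004",
    "pregnanes": "OCB:0000005",
    "5α-pregnanes": "OCB:0000006",
    "5β-pregnanes": "OCB:0000007",
}

#: bare steroid ring system (three fused cyclohexanes + one cyclopentane)
GONANE = "C12CCCCC1CCC1C2CCC2C1CCC2"
#: androstane skeleton: gonane + angular methyls at C-10 and C-13 (19 C)
ANDROSTANE = "CC12CCCCC1CCC1C2CCC2(C)C1CCC2"
#: pregnane skeleton: androstane + ethyl at C-17 (21 C)
PREGNANE = "CC12CCCCC1CCC1C2CCC2(C)C1CCC2CC"
#: C-17 carbon-substitution exclusions; both valence cases must be
#: named: a single-bonded carbon and a double-bonded one (e.g. a
#: 17-methylene group); an oxygen at C-17 (17-keto, 17-ol) is allowed
ANDROSTANE_C17_FORBIDDEN = [ANDROSTANE + "[#6]", ANDROSTANE + "=[#6]"]

#: ring-fusion stereochemistry at C-5/C-10, no atom lists
STEREO_5A = "C[C@]12CCCC[C@@H]1CCC1C2CCC2(C)C1CCC2"
STEREO_5B = "C[C@]12CCCC[C@H]1CCC1C2CCC2(C)C1CCC2"
#: atom-list partners (flexible C-3 / C-17 hybridization), no stereo
ATOMLIST_ANDRO = "CC12CC[CX4,CX3]CC1CCC1C2CCC2(C)C1CC[CX4,CX3]2"
ATOMLIST_PREG = "CC12CC[CX4,CX3]CC1CCC1C2CCC2(C)C1CCC2CC"

_B_NODES = [
    ("steroids", [], [GONANE], [], ["steranes"]),
    ("androstanes", ["steroids"], [ANDROSTANE],
     ANDROSTANE_C17_FORBIDDEN, []),
    ("5α-androstanes", ["androstanes"],
     [STEREO_5A + " & " + ATOMLIST_ANDRO], ANDROSTANE_C17_FORBIDDEN,
     ["5-alpha-androstanes", "5a-androstanes"]),
    ("5β-androstanes", ["androstanes"],
     [STEREO_5B + " & " + ATOMLIST_ANDRO], ANDROSTANE_C17_FORBIDDEN,
     ["5-beta-androstanes", "5b-androstanes"]),
    ("pregnanes", ["steroids"], [PREGNANE], [], []),
    ("5α-pregnanes", ["pregnanes"],
     [STEREO_5A + " & " + ATOMLIST_PREG], [], ["5-alpha-pregnanes"]),
    ("5β-pregnanes", ["pregnanes"],
     [STEREO_5B + " & " + ATOMLIST_PREG], [], ["5-beta-pregnanes"]),
]


def build_ontology_B() -> ChemOntology:
    """Steroid expert-knowledge fixture ontology."""
    ont = ChemOntology(header=[("format-version", "1.2"),
                               ("ontology", "ontoclass-fixture-B")])
    for name, parents, allowed, forbidden, synonyms in _B_NODES:
        from .logic import parse_logic_lines
        lines = allowed + ["!" + f for f in forbidden]
        a, f = parse_logic_lines(lines, term=B[name])
        ont.add_node(ClassNode(id=B[name], name=name, synonyms=list(synonyms),
                               definition=compile_definition(a, f, term=B[name])))
    for name, parents, *_ in _B_NODES:
        for p in parents:
            ont.add_edge(B[name], B[p])
    return ont


# ---------------------------------------------------------------------------
# labeled molecules

@dataclass(frozen=True)
class LabeledMolecule:
    """A molecule with generator-guaranteed class labels.

    ``truth_labels`` is ancestor-closed against the fixture ontology;
    ``decoy_of`` names the class the molecule deliberately just-misses,
    with the miss reason recorded.
    """

    smiles: str
    truth_labels: frozenset[str]
    decoy_of: Optional[str] = None
    reason: Optional[str] = None


# (smiles, directly-satisfied class names, decoy-of name, reason)
_POOL_A = [
    # cycloalkanes: saturated carbocyclic rings, optionally alkylated
    ("C1CC1", ("carbon compounds", "cyclic compounds", "cycloalkanes"), None, None),
    ("C1CCCC1", ("carbon compounds", "cyclic compounds", "cycloalkanes"), None, None),
    ("C1CCCCC1", ("carbon compounds", "cyclic compounds", "cycloalkanes"), None, None),
    ("C1CCCCCC1", ("carbon compounds", "cyclic compounds", "cycloalkanes"), None, None),
    ("CC1CCCCC1", ("carbon compounds", "cyclic compounds", "cycloalkanes"), None, None),
    ("CCC1CCCCC1", ("carbon compounds", "cyclic compounds", "cycloalkanes"), None, None),
    ("CC1CCC(C)CC1", ("carbon compounds", "cyclic compounds", "cycloalkanes"), None, None),
    ("CC1(C)CCCCC1", ("carbon compounds", "cyclic compounds", "cycloalkanes"), None, None),
    ("CC1CCCC1C", ("carbon compounds", "cyclic compounds", "cycloalkanes"), None, None),
    ("C1CCC2CCCCC2C1", ("carbon compounds", "cyclic compounds", "cycloalkanes"), None, None),
    # cycloalkane decoys: one violating feature each
    ("c1ccccc1", ("carbon compounds", "cyclic compounds", "aromatic compounds"),
     "cycloalkanes", "aromatic ring bonds"),
    ("C1=CCCCC1", ("carbon compounds", "cyclic compounds"),
     "cycloalkanes", "ring double bond"),
    ("ClC1CCCCC1", ("carbon compounds", "cyclic compounds", "hetero compounds",
                    "organohalogen compounds"),
     "cycloalkanes", "non-carbon atom present"),
    # acyclic alkanes
    ("C", ("carbon compounds",), None, None),
    ("CC", ("carbon compounds",), None, None),
    ("CCC", ("carbon compounds",), None, None),
    ("CCCC", ("carbon compounds",), None, None),
    ("Cc1ccccc1", ("carbon compounds", "cyclic compounds",
                   "aromatic compounds"), None, None),
    # primary amines
    ("CN", ("carbon compounds", "hetero compounds", "amines",
            "primary amines"), None, None),
    ("CCN", ("carbon compounds", "hetero compounds", "amines",
             "primary amines"), None, None),
    ("CCCN", ("carbon compounds", "hetero compounds", "amines",
              "primary amines"), None, None),
    ("CC(C)N", ("carbon compounds", "hetero compounds", "amines",
                "primary amines"), None, None),
    ("CCCCN", ("carbon compounds", "hetero compounds", "amines",
               "primary amines"), None, None),
    ("CC(C)(C)N", ("carbon compounds", "hetero compounds", "amines",
                   "primary amines"), None, None),
    ("NCCCCN", ("carbon compounds", "hetero compounds", "amines",
                "primary amines"), None, None),
    ("Nc1ccccc1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                   "aromatic compounds", "amines", "primary amines"), None, None),
    ("NC1CCCCC1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                   "amines", "primary amines"), None, None),
    # secondary / tertiary amines
    ("CNC", ("carbon compounds", "hetero compounds", "amines"), None, None),
    ("CCNCC", ("carbon compounds", "hetero compounds", "amines"), None, None),
    ("CN(C)C", ("carbon compounds", "hetero compounds", "amines"), None, None),
    ("C1CCNCC1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                  "amines"), None, None),
    # amine decoys: acyl group turns the amine into an amide
    ("CC(N)=O", ("carbon compounds", "hetero compounds",
                 "carboxylic acid derivatives"),
     "primary amines", "nitrogen acylated (amide)"),
    ("CC(=O)NC", ("carbon compounds", "hetero compounds",
                  "carboxylic acid derivatives"),
     "amines", "nitrogen acylated (amide)"),
    ("CCC#N", ("carbon compounds", "hetero compounds"),
     "amines", "nitrile nitrogen is not three-valent sp3"),
    # dialkyl ethers
    ("COC", ("carbon compounds", "hetero compounds", "ethers",
             "dialkyl ethers"), None, None),
    ("CCOC", ("carbon compounds", "hetero compounds", "ethers",
              "dialkyl ethers"), None, None),
    ("CCOCC", ("carbon compounds", "hetero compounds", "ethers",
               "dialkyl ethers"), None, None),
    ("CCOC(C)C", ("carbon compounds", "hetero compounds", "ethers",
                  "dialkyl ethers"), None, None),
    ("CCCOCCC", ("carbon compounds", "hetero compounds", "ethers",
                 "dialkyl ethers"), None, None),
    ("COCCOC", ("carbon compounds", "hetero compounds", "ethers",
                "dialkyl ethers"), None, None),
    ("C1CCOC1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                 "ethers", "dialkyl ethers"), None, None),
    ("C1CCOCC1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                  "ethers", "dialkyl ethers"), None, None),
    # alkyl aryl ethers
    ("COc1ccccc1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                    "aromatic compounds", "ethers", "alkyl aryl ethers"),
     None, None),
    ("CCOc1ccccc1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                     "aromatic compounds", "ethers", "alkyl aryl ethers"),
     None, None),
    ("COc1ccc(C)cc1", ("carbon compounds", "hetero compounds",
                       "cyclic compounds", "aromatic compounds", "ethers",
                       "alkyl aryl ethers"), None, None),
    # diaryl ethers
    ("O(c1ccccc1)c1ccccc1", ("carbon compounds", "hetero compounds",
                             "cyclic compounds", "aromatic compounds",
                             "ethers", "diaryl ethers"), None, None),
    ("Cc1ccccc1Oc1ccccc1", ("carbon compounds", "hetero compounds",
                            "cyclic compounds", "aromatic compounds",
                            "ethers", "diaryl ethers"), None, None),
    # ether decoys: ester oxygen posing as an ether; aromatic ring oxygen
    ("CCOC(C)=O", ("carbon compounds", "hetero compounds",
                   "carboxylic acid derivatives"),
     "dialkyl ethers", "oxygen bound to a carbonyl carbon (ester)"),
    ("COC(=O)CC", ("carbon compounds", "hetero compounds",
                   "carboxylic acid derivatives"),
     "dialkyl ethers", "oxygen bound to a carbonyl carbon (ester)"),
    ("c1ccoc1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                 "aromatic compounds"),
     "ethers", "aromatic ring oxygen"),
    # alcohols
    ("CO", ("carbon compounds", "hetero compounds", "alcohols"), None, None),
    ("CCO", ("carbon compounds", "hetero compounds", "alcohols"), None, None),
    ("CCCO", ("carbon compounds", "hetero compounds", "alcohols"), None, None),
    ("CC(C)O", ("carbon compounds", "hetero compounds", "alcohols"), None, None),
    ("CC(C)(C)O", ("carbon compounds", "hetero compounds", "alcohols"), None, None),
    ("OCCO", ("carbon compounds", "hetero compounds", "alcohols"), None, None),
    ("OCC1CCCCC1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                    "alcohols"), None, None),
    ("OCc1ccccc1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                    "aromatic compounds", "alcohols"), None, None),
    ("Oc1ccccc1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                   "aromatic compounds"),
     "alcohols", "hydroxyl on aromatic carbon (phenol)"),
    # carboxylic acids (narrow) and derivatives (broad)
    ("OC=O", ("carbon compounds", "hetero compounds", "carboxylic acids"),
     None, None),
    ("CC(=O)O", ("carbon compounds", "hetero compounds", "carboxylic acids"),
     None, None),
    ("CCC(=O)O", ("carbon compounds", "hetero compounds", "carboxylic acids"),
     None, None),
    ("CC(C)C(=O)O", ("carbon compounds", "hetero compounds",
                     "carboxylic acids"), None, None),
    ("OC(=O)c1ccccc1", ("carbon compounds", "hetero compounds",
                        "cyclic compounds", "aromatic compounds",
                        "carboxylic acids"), None, None),
    ("OC(=O)C1CCCCC1", ("carbon compounds", "hetero compounds",
                        "cyclic compounds", "carboxylic acids"), None, None),
    ("CC(=O)OC(C)=O", ("carbon compounds", "hetero compounds",
                       "carboxylic acid derivatives"), None, None),
    ("CC(=O)Cl", ("carbon compounds", "hetero compounds",
                  "carboxylic acid derivatives", "organohalogen compounds"),
     None, None),
    # organohalogen compounds
    ("CCl", ("carbon compounds", "hetero compounds",
             "organohalogen compounds"), None, None),
    ("CCCl", ("carbon compounds", "hetero compounds",
              "organohalogen compounds"), None, None),
    ("CCBr", ("carbon compounds", "hetero compounds",
              "organohalogen compounds"), None, None),
    ("CCI", ("carbon compounds", "hetero compounds",
             "organohalogen compounds"), None, None),
    ("ClCCCl", ("carbon compounds", "hetero compounds",
                "organohalogen compounds"), None, None),
    ("Clc1ccccc1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                    "aromatic compounds", "organohalogen compounds"),
     None, None),
    # imidazoles; benzimidazole fails the single-ring-membership rule
    ("c1cnc[nH]1", ("carbon compounds", "hetero compounds", "cyclic compounds",
                    "aromatic compounds", "imidazoles"), None, None),
    ("CCc1ncc[nH]1", ("carbon compounds", "hetero compounds",
                      "cyclic compounds", "aromatic compounds", "imidazoles"),
     None, None),
    ("Cc1ncc[nH]1", ("carbon compounds", "hetero compounds",
                     "cyclic compounds", "aromatic compounds", "imidazoles"),
     None, None),
    ("c1ccc2[nH]cnc2c1", ("carbon compounds", "hetero compounds",
                          "cyclic compounds", "aromatic compounds"),
     "imidazoles", "imidazole ring fused to a second ring"),
    # multi-functional molecules (several concurrent categories)
    ("NCCOCCO", ("carbon compounds", "hetero compounds", "amines",
                 "primary amines", "ethers", "dialkyl ethers", "alcohols"),
     None, None),
    ("OCCOCCCl", ("carbon compounds", "hetero compounds", "ethers",
                  "dialkyl ethers", "alcohols", "organohalogen compounds"),
     None, None),
    ("CC(O)COc1ccc(Cl)cc1", ("carbon compounds", "hetero compounds",
                             "cyclic compounds", "aromatic compounds",
                             "ethers", "alkyl aryl ethers", "alcohols",
                             "organohalogen compounds"), None, None),
    ("NCC(=O)O", ("carbon compounds", "hetero compounds", "amines",
                  "primary amines", "carboxylic acids"), None, None),
    ("NCCc1ccc(OC)cc1", ("carbon compounds", "hetero compounds",
                         "cyclic compounds", "aromatic compounds", "amines",
                         "primary amines", "ethers", "alkyl aryl ethers"),
     None, None),
    # exact-compound members
    (R_LACTIC, ("carbon compounds", "hetero compounds", "alcohols",
                "carboxylic acids", "(R)-lactic acid"), None, None),
    (S_LACTIC, ("carbon compounds", "hetero compounds", "alcohols",
                "carboxylic acids", "(S)-lactic acid"), None, None),
    (FLAT_LACTIC, ("carbon compounds", "hetero compounds", "alcohols",
                   "carboxylic acids", "lactic acid"), None, None),
    (GLUCOSE_REPRESENTATIONS[2], ("carbon compounds", "hetero compounds",
                                  "alcohols", "D-glucose"), None, None),
    (GLUCOSE_REPRESENTATIONS[0], ("carbon compounds", "hetero compounds",
                                  "cyclic compounds", "alcohols", "ethers",
                                  "dialkyl ethers", "D-glucose"), None, None),
    (GLUCOSE_REPRESENTATIONS[1], ("carbon compounds", "hetero compounds",
                                  "cyclic compounds", "alcohols", "ethers",
                                  "dialkyl ethers", "D-glucose"), None, None),
    # inorganic: classified only as hetero compounds
    ("[Na+].[Cl-]", ("hetero compounds",), None, None),
    ("O", ("hetero compounds",), None, None),
]


def _close(ontology: ChemOntology, names: tuple[str, ...],
           id_map: dict) -> frozenset[str]:
    ids = {id_map[n] for n in names}
    closed = set(ids)
    for i in ids:
        closed |= ontology.ancestors(i)
    return frozenset(closed)


def labeled_pool(ontology: Optional[ChemOntology] = None) -> list[LabeledMolecule]:
    """The full authored pool of labeled molecules for ontology A."""
    ont = ontology or build_ontology_A()
    return [
        LabeledMolecule(
            smiles=smi,
            truth_labels=_close(ont, names, A),
            decoy_of=A[decoy] if decoy else None,
            reason=reason,
        )
        for smi, names, decoy, reason in _POOL_A
    ]


def generate_labeled_set(seed: int, n: int) -> list[LabeledMolecule]:
    """Deterministically sample ``n`` labeled molecules for ontology A.

    When ``n`` exceeds the enumerable pool diversity, sampling falls
    back to replacement (with a warning).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = labeled_pool()
    rng = random.Random(seed)
    if n <= len(pool):
        return rng.sample(pool, n)
    warnings.warn(
        f"requested {n} molecules from a pool of {len(pool)}; "
        "sampling with replacement", stacklevel=2)
    return [rng.choice(pool) for _ in range(n)]


# steroid skeleton probes for ontology B ------------------------------------

ANDROSTANE_5A = "C[C@]12CCC[C@@H]1[C@@H]1CC[C@H]3CCCC[C@]3(C)[C@H]1CC2"
ANDROSTANE_5B = "C[C@]12CCC[C@@H]1[C@@H]1CC[C@@H]3CCCC[C@]3(C)[C@H]1CC2"
PREGNANE_5A = "CCC1CC[C@@H]2[C@@H]3CC[C@H]4CCCC[C@]4(C)[C@H]3CC[C@@]12C"
PREGNANE_5B = "CCC1CC[C@@H]2[C@@H]3CC[C@@H]4CCCC[C@]4(C)[C@H]3CC[C@@]12C"
ANDROSTANONE_17_5A = "C[C@]12CCCC[C@@H]1CC[C@H]1[C@H]3CCC(=O)[C@]3(C)CC[C@@H]12"
ANDROSTANOL_17_5B = "C[C@]12CCCC[C@H]1CC[C@H]1[C@H]3CCC(O)[C@]3(C)CC[C@@H]12"
ANDROSTANOL_3_5A = "C[C@]12CCC[C@@H]1[C@@H]1CC[C@H]3CC(O)CC[C@]3(C)[C@H]1CC2"
METHYLENE_17_5A = "C=C1CC[C@@H]2[C@@H]3CC[C@H]4CCCC[C@]4(C)[C@H]3CC[C@@]12C"

_POOL_B = [
    (ANDROSTANE, ("steroids", "androstanes"), None, None),
    (ANDROSTANE_5A, ("steroids", "androstanes", "5α-androstanes"),
     None, None),
    (ANDROSTANE_5B, ("steroids", "androstanes", "5β-androstanes"),
     None, None),
    (PREGNANE, ("steroids", "pregnanes"), "androstanes",
     "carbon substituent at C-17 (single bond)"),
    (PREGNANE_5A, ("steroids", "pregnanes", "5α-pregnanes"),
     "androstanes", "carbon substituent at C-17 (single bond)"),
    (PREGNANE_5B, ("steroids", "pregnanes", "5β-pregnanes"),
     "androstanes", "carbon substituent at C-17 (single bond)"),
    (ANDROSTANONE_17_5A, ("steroids", "androstanes", "5α-androstanes"),
     None, None),
    (ANDROSTANOL_17_5B, ("steroids", "androstanes", "5β-androstanes"),
     None, None),
    (ANDROSTANOL_3_5A, ("steroids", "androstanes", "5α-androstanes"),
     None, None),
    (METHYLENE_17_5A, ("steroids",), "androstanes",
     "carbon substituent at C-17 (double bond)"),
    (GONANE, ("steroids",), "androstanes", "angular methyl groups missing"),
    ("C1CCC2CCCCC2C1", (), "steroids", "only two fused rings (decalin)"),
]


def steroid_probes(ontology: Optional[ChemOntology] = None) -> list[LabeledMolecule]:
    """Labeled steroid skeleton probes for ontology B."""
    ont = ontology or build_ontology_B()
    return [
        LabeledMolecule(
            smiles=smi,
            truth_labels=_close(ont, names, B),
            decoy_of=B[decoy] if decoy else None,
            reason=reason,
        )
        for smi, names, decoy, reason in _POOL_B
    ]


def write_fixtures(outdir, seed: int = 1, n: int = 200) -> list[Path]:
    """Write the fixture ontologies and a labeled molecule set to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    for fname, ont in (("A-replica.obo", build_ontology_A()),
                       ("B-replica.obo", build_ontology_B())):
        path = outdir / fname
        path.write_text(serialize_obo(ont))
        written.append(path)

    labeled = generate_labeled_set(seed, n)
    smi_path = outdir / "labeled_set.smi"
    with open(smi_path, "w") as fh:
        for i, lm in enumerate(labeled, start=1):
            fh.write(f"{lm.smiles} mol{i:04d}\n")
    written.append(smi_path)

    tsv_path = outdir / "labels.tsv"
    with open(tsv_path, "w") as fh:
        fh.write(f"# seed={seed} n={n}\n")
        fh.write("source_id\tsmiles\ttruth_labels\tdecoy_of\treason\n")
        for i, lm in enumerate(labeled, start=1):
            fh.write("\t".join([
                f"mol{i:04d}", lm.smiles, "|".join(sorted(lm.truth_labels)),
                lm.decoy_of or "", lm.reason or "",
            ]) + "\n")
    written.append(tsv_path)
    return written
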
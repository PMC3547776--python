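# Methods

## Model

A chemical class is a node in a directed acyclic graph of `is_a`
relationships carrying an optional structural definition of one of two
kinds:

* **Class logic** — two OR-sets of *match units*, combined as
  `(allowed-1 OR allowed-2 OR ...) AND NOT (forbidden-1 OR ...)`. A
  unit is a conjunction of one or more SMARTS patterns that must each
  have at least one substructure embedding. A molecule satisfies the
  definition iff some allowed unit matches and no forbidden unit
  matches anywhere in the molecule (forbidden semantics are
  molecule-global: a single embedding of any forbidden unit rejects).
  A definition with no allowed units is abstract and matches nothing
  directly.
* **Exact compound** — an OR-set of complete connection tables
  (SMILES). Membership is equality of the structure key — standard
  InChI after normalization — with at least one representation.
  Tautomers, microspecies and ring/chain forms of one compound are
  separate representations of the same node; enantiomers get distinct
  nodes because the InChI stereo layer distinguishes them.

Assignment applies subsumption gating: a compound belongs to a node
iff it satisfies the node's own definition and the class logic of
every ancestor. The per-compound result is the ancestor closure of
all such nodes; reporting keeps the *deepest* nodes (members with no
assigned descendant), an antichain that may span several branches.

Two readings deserve justification:

* *Ancestor exact-compound nodes impose nothing on descendants.* Only
  class logic is inherited. A stereo-defined child compound placed
  under its stereo-undefined parent compound could never satisfy the
  parent's exact-identity key; the lactic-acid family (parent
  `CC(O)C(=O)O`, children (R)-, (S)- and rac-lactic acid) is exactly
  this shape, so inheritance is restricted to SMARTS members.
* *Abstract definitions match nothing directly.* An allowed-empty
  definition could be read as vacuously true; that would assign every
  molecule to every abstract class. Abstract classes are instead
  populated through structurally defined descendants and via closure.

## SMARTS dialect and matching

Daylight semantics as implemented by RDKit; RDKit's default
aromaticity perception is canonical for molecules and patterns alike.
All matching passes `useChirality=True`, so `@`/`@@` in patterns are
honoured. Two practical consequences are documented rather than
worked around:

* *Hydrogen-explicit patterns.* Patterns that name hydrogens as graph
  atoms (`[H]`, `[#1]`) are evaluated against a hydrogen-explicit copy
  of the molecule (detected per pattern from the compiled query);
  otherwise hydrogen-complete connection-table patterns could never
  embed. Patterns without explicit hydrogens see the heavy-atom graph.
* *Chiral neighbor order.* The implicit hydrogen of a chiral SMARTS
  atom occupies a position in the neighbor ordering that depends on
  where the atom sits in the string: `C[C@@H](O)C(O)=O` and
  `[C@@H](C)(O)C(O)=O` denote opposite parities. Stereo patterns in
  the fixtures are therefore written in the same atom order as the
  molecule SMILES they are meant to match, and the test suite pins
  the behaviour.

Within a unit, AND-ed patterns must each match *somewhere* in the
molecule; the embeddings need not overlap. The intended use (one
pattern carrying stereochemistry, one carrying atom lists, both
describing the same scaffold) makes overlap the common case, but
overlap is not enforced — the weaker contract is testable without
deciding subgraph-overlap questions, and the fixture scaffolds are
rigid enough that distinct-embedding false positives cannot arise.

An enumerated element blacklist ("any atom other than carbon and
hydrogen") is written as the single negated pattern `[!#6;!#1]`
rather than a 100-element atom list; the semantics are identical.

## Normalization and identity

`normalize` sanitizes, perceives aromaticity and unifies salt forms.
Covalent alkali-metal/halogen single bonds are split into the ionic
form (`[Na][Cl]` → `[Na+].[Cl-]`); the ionic direction was chosen as
canonical because it is also what InChI's metal disconnection layer
produces, keeping the molecule graph and the identity key consistent.
Normalization is idempotent.

The structure key is standard InChI: invariant to input atom
ordering, hydrogen notation and kekulization, while retaining stereo
and isotope layers (whether isotopologues are synonyms or child nodes
is left to ontology authors — the key keeps them distinct either
way). Tautomer canonicalization exists behind a config flag but
defaults off: compound nodes represent tautomers as explicit OR-sets,
and collapsing them would make those representations collide.

Mixture detection counts connected components after normalization; a
small whitelist of counter-ion fragments (Li⁺/Na⁺/K⁺/Rb⁺/Cs⁺,
F⁻/Cl⁻/Br⁻/I⁻, NH₄⁺) is treated as salt components rather than
mixture members, so sodium acetate is one compound while two ethanol
fragments are a mixture. Mixtures are classified as-is and flagged;
`skip_mixtures` excludes them instead.

## Reasoning

Graph checks use the child→parent digraph: elementary cycles
(`networkx.simple_cycles`, each reported once, rotated to start at the
smallest id) and redundant edges (original edges minus the transitive
reduction). Chemical consistency is *probe-based*: for every probe
molecule satisfying a node's own definition, any ancestor class logic
the probe fails is reported, and every exact-compound representation
is checked against its own ancestors' class logic. Symbolic SMARTS
subsumption is undecidable in practice, so the guarantee extends
exactly to the supplied probe pool. Violations are warnings
(`validate` exit code 1), since they are editor aids, and redundant
links are reported, never auto-deleted.

## Fixture ontologies

**A** (22 terms, depth 5) covers functional groups under one abstract
root with structural top-level nodes (carbon / cyclic / hetero /
aromatic compounds). The leaf definitions were chosen so that every
subclass provably implies its ancestors over the probe pool (e.g.
dialkyl ethers `[O;X2;!a]([CX4])[CX4]` implies the ether pattern,
which itself excludes carbonyl neighbors so esters are not ethers).
The imidazole class restricts each ring atom to exactly one ring
(`R1`), keeping fused benzimidazole out — fused ring systems are a
distinct class, not substituted monocycles. *Carboxylic acids*
(narrow) and *carboxylic acid derivatives* (broad, `oc_scope: broad`)
sit at the same hierarchical level.

**B** (7 terms) encodes steroid expert knowledge. Although pregnane
contains the androstane skeleton as a substructure, pregnanes are not
androstane derivatives; the androstane classes therefore carry two
forbidden units — the skeleton with a single-bonded and with a
double-bonded extra carbon at C-17 — so that only carbon substitution
at C-17 excludes (a 17-keto or 17-ol androstane remains an
androstane). All androstane-family nodes carry these units themselves
as well as inheriting them; without the local copies, the 5α/5β
allowed units would over-match the sibling pregnane branch and the
probe-based consistency check would (correctly) complain. The 5α/5β
subclasses use one AND unit pairing a C-5/C-10 stereo pattern with an
atom-list pattern (flexible C-3/C-17 hybridization). The scaffold
SMILES are authored, validated by ring/atom-count assertions (four
fused 6-6-6-5 rings; 17/19/21 carbons for gonane/androstane/
pregnane), and the C-5 epimer labels were fixed by a one-off 3D
analysis of the H5–C5–C10–C19 torsion (≈180° trans fusion → 5α, ≈40°
cis → 5β); the absolute enantiomer choice is internal and consistent
between patterns and generated molecules.

## Labeled generator

`generate_labeled_set(seed, n)` samples from an authored pool of 90
molecules: true members of each class (ring sizes, alkyl decoration),
decoys that each miss one class for one recorded reason, exact-
compound members (lactic acids, glucose forms), inorganic salts, and
multi-functional molecules carrying three or more concurrent defined
labels. Truth labels are authored per molecule as the set of directly
satisfied classes and ancestor-closed against the ontology graph (a
graph operation, independent of the classifier). Sampling is
deterministic per seed; requests beyond the pool size fall back to
replacement with a warning. Default n = 200 gives every pool member
high probability of inclusion while keeping the closed-loop check
under a second.

What the generator does *not* emulate: tautomer-rich chemistry,
charged microspecies beyond simple salts, polymers/Markush structures
(out of scope by design), and database-scale diversity. A perfect
closed-loop precision/recall therefore certifies that the logic,
inheritance and deepest-node machinery are internally correct — not
that any particular real-world ontology is complete.

## Numerical and procedural choices

* Determinism: serialization sorts terms by id and tags in a fixed
  order; annotation tables sort class-id lists; identical inputs give
  byte-identical outputs. All randomized tests and the acceptance
  script derive their RNG state from an explicit seed.
* Problem sizes: 1,000 randomized pairs for the logic oracle, 60
  random DAGs (≤30 nodes) for the reasoner oracle, n = 200 for the
  closed loop — sizes at which the whole acceptance run completes in
  about a second while exercising every code path.
* Degenerate inputs: unparseable records are flagged and carried, never
  dropped or fatal; empty ontologies serialize to a header; empty
  batches produce empty summaries; cyclic graphs make redundancy and
  consistency checks refuse (with the cycles themselves reported)
  rather than loop.
* Term mining captures a one-token window next to the cue words
  (suffix cues: analogue(s)/analog(s), derivative(s), scaffold(s),
  skeleton(s), backbone(s); prefix cue: substituted), keeps hyphenated
  tokens whole, drops captures that are themselves cues or contain no
  letter, and ranks by frequency with a lexicographic tie-break. The
  window is configurable; multi-word chemical names are beyond the
  heuristic.

## Known limitations

* Consistency checking is only as strong as the probe pool; it cannot
  prove two SMARTS definitions compatible in general.
* Within-unit AND does not constrain embeddings to overlap.
* The ether definition accepts cyclic ethers and the ring oxygen of
  sugar hemiacetal forms; finer functional-group discrimination is an
  ontology-authoring matter, not an engine matter.
* Polymers, Markush structures and metallo-organic compounds that
  valence-bond connection tables cannot represent are out of scope.
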
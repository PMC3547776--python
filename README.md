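# ontoclass

Rule-based classification of chemical compounds into an expert
ontology of compound classes.

Manually curated chemical ontologies (MeSH, ChEBI) assign compounds to
classes by hand, which does not scale to database-sized inputs and is
error-prone. `ontoclass` implements the alternative: every compound
class carries a *structural definition* — a boolean combination of
SMARTS substructure expressions — inside a directed acyclic `is_a`
hierarchy, so that any structure file can be annotated automatically
and reproducibly.

## The classification model

A class definition is a formula over SMARTS match units:

```
(SMARTS-1 OR SMARTS-2 OR ...) AND NOT (SMARTS-x OR SMARTS-x+1 OR ...)
```

* **Allowed units** (OR): at least one must embed in the molecule.
* **Forbidden units** (OR, negated): none may embed anywhere. This is
  what makes definitions like *cycloalkanes* —
  `[#6R]@[#6R] AND NOT ([#6R]:[#6R] OR [#6R]#[#6R] OR [#6R]=[#6R] OR [!#6;!#1])`
  — or the exclusion of C-17-substituted steroids from *androstanes*
  expressible at all; plain substructure search cannot say "must not
  contain".
* **AND units**: one unit may conjoin several SMARTS that must all hit,
  e.g. a stereochemistry-bearing pattern paired with an atom-list
  pattern (atom lists break R/S priority assignment, so the two
  constraints are written separately).
* **Exact compounds**: a class may instead be an OR-set of full
  connection tables (tautomers, microspecies, ring/chain forms);
  membership is identity of the standard-InChI structure key after
  normalization.
* **Inheritance**: `is_a` is transitive and directional; a compound is
  assigned to a class only if it satisfies the class's own definition
  *and* every ancestor's SMARTS logic. Classes without a definition
  are abstract and are populated through their descendants.
* **Deepest-node reporting**: per compound, the assigned classes with
  no assigned descendant — an antichain that may span several
  branches, since one molecule legitimately sits in many categories.

Two built-in fixture ontologies exercise all of this: **A** (functional
groups: an ether subtree, amines, cycloalkanes, narrow/broad
carboxylic-acid classes, exact-compound nodes for the lactic acid
stereoisomers and the three forms of D-glucose) and **B** (steroid
expert knowledge: androstanes vs pregnanes as siblings, 5α/5β
ring-fusion stereochemistry), plus a generator of labeled test
molecules with decoys.

## Worked example

```
$ ontoclass fixtures --out fixtures
$ cat compounds.smi
CCOCC diethyl_ether
COc1ccccc1 anisole
CC(N)=O acetamide
C1CCCCC1 cyclohexane
NCCOCCO aminoethoxyethanol
$ ontoclass classify --ontology fixtures/A-replica.obo \
    --in compounds.smi --out annotations.tsv --summary summary.tsv
```

`annotations.tsv` (abridged):

```
source_id           smiles      deepest_classes                          all_classes
diethyl_ether       CCOCC       OCA:0000010                              OCA:0000001|OCA:0000002|OCA:0000004|OCA:0000009|OCA:0000010
anisole             COc1ccccc1  OCA:0000011                              OCA:0000001|OCA:0000002|OCA:0000003|OCA:0000004|OCA:0000005|OCA:0000009|OCA:0000011
acetamide           CC(N)=O     OCA:0000015                              OCA:0000001|OCA:0000002|OCA:0000004|OCA:0000015
cyclohexane         C1CCCCC1    OCA:0000006                              OCA:0000001|OCA:0000002|OCA:0000003|OCA:0000006
aminoethoxyethanol  NCCOCCO     OCA:0000008|OCA:0000010|OCA:0000013      OCA:0000001|OCA:0000002|OCA:0000004|OCA:0000007|OCA:0000008|OCA:0000009|OCA:0000010|OCA:0000013
```

Reading the output: diethyl ether lands at *dialkyl ethers*
(OCA:0000010), with the full ancestor closure (*ethers*, *hetero
compounds*, *carbon compounds*, root) in `all_classes`. Anisole is an
*alkyl aryl ether*, not a dialkyl ether. Acetamide is a *carboxylic
acid derivative* and — because the forbidden acyl environment fires —
**not** a primary amine. Aminoethoxyethanol shows a multi-branch
antichain: deepest nodes *primary amines*, *dialkyl ethers* and
*alcohols* simultaneously. `summary.tsv` adds per-class deepest-node
frequencies and the mean number of direct (4.6) and closure (5.6)
assignments per compound.

Other commands: `ontoclass validate <obo> [--probes probes.smi]`
(cycle, redundant-link and chemistry-consistency lint; exit code 0
clean / 1 findings / 2 fatal), `ontoclass stats <obo>` (node counts,
DAG depth), `ontoclass mine-terms` (cue-word mining of class-term
candidates from text). File formats, including the `oc_smarts` /
`oc_smiles` / `oc_scope` OBO dialect, are specified in
[FORMAT.md](FORMAT.md); the science and its design choices in
[docs/methods.md](docs/methods.md).

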
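# ontoclass file formats

## Structure-logic lines

A class definition is a list of *logic lines*. Each line is one match
unit; all lines of one term combine into a single boolean formula:

```
(allowed-unit-1 OR allowed-unit-2 OR ...) AND NOT (forbidden-unit-1 OR ...)
```

Bit-exact line syntax:

* One unit per line.
* A leading `!` (immediately before the first pattern, no space
  required after it) marks the unit as **forbidden**. All other lines
  are **allowed** units.
* Within a unit, ` & ` (space, ampersand, space) separates SMARTS
  patterns that must **all** have at least one embedding in the
  molecule. The separator must include both spaces; ampersands inside
  SMARTS brackets (high-precedence AND of atom primitives) are never
  surrounded by spaces and are not affected.
* A unit matches a molecule iff every one of its patterns has at least
  one substructure embedding (anywhere in the molecule; the embeddings
  need not overlap).
* A molecule satisfies the definition iff at least one allowed unit
  matches and no forbidden unit matches. A definition with no allowed
  lines is *abstract* and matches no molecule directly.

Example (cycloalkanes):

```
[#6R]@[#6R]
![#6R]:[#6R]
![#6R]#[#6R]
![#6R]=[#6R]
![!#6;!#1]
```

Example of an AND unit pairing a stereochemistry pattern with an
atom-list pattern:

```
C[C@]12CCCC[C@@H]1CCC1C2CCC2(C)C1CCC2 & CC12CC[CX4,CX3]CC1CCC1C2CCC2(C)C1CC[CX4,CX3]2
```

## OBO dialect

Ontologies are OBO 1.2 flat files. Beyond the standard tags (`id`,
`name`, `synonym`, `is_a`), three dialect tags are used inside `[Term]`
stanzas:

| tag | value | meaning |
|-----|-------|---------|
| `oc_smarts` | one logic line (syntax above) | one match unit of the class definition |
| `oc_smiles` | one SMILES string | one exact connection-table representation of a compound term |
| `oc_scope`  | `narrow` or `broad` | class scope; default `narrow` |

Rules:

* A term may carry `oc_smarts` lines or `oc_smiles` lines, never both.
* A term with neither is abstract (populated via its descendants).
* `oc_smiles` terms list one representation per tag line; a molecule
  belongs to the term iff its structure key (standard InChI after
  normalization) equals that of at least one representation (OR
  logic). Tautomers, microspecies and ring/chain forms are written as
  separate representations.
* `is_a` values may carry a trailing `! name` comment, which is
  ignored on parsing. `oc_smarts` values are never comment-stripped
  (SMARTS contain `!`).
* Unknown tags are preserved verbatim and re-emitted on serialization.

Serialization is deterministic: terms sorted by id; tags emitted in
the order `id`, `name`, `synonym`, `oc_scope`, `oc_smarts` (allowed
units first, then forbidden), `oc_smiles`, `is_a` (sorted), then any
preserved unknown tags.

## Structure input

* `.smi` — one record per line: `SMILES[ whitespace id]`. Lines
  starting with `#` and blank lines are skipped. Records whose SMILES
  does not parse are kept and flagged, not dropped.
* `.sdf` — V2000 SD files; records split on `$$$$`.

## Annotation output (TSV)

Columns: `source_id`, `smiles` (canonical, after normalization),
`deepest_classes` (pipe-joined ids), `all_classes` (pipe-joined,
ancestor-closed; empty when `--deepest-only`), `mixture_flag` (0/1),
`error`. Class-id lists are sorted, so identical input yields
byte-identical output.
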
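"""Boolean SMARTS logic for chemical class definitions.

A chemical class is described by two sets of *match units*:

* ``allowed`` units, combined by OR — at least one must hit;
* ``forbidden`` units, combined by OR — none may hit anywhere in the
  molecule.

A unit is a conjunction of one or more SMARTS patterns that must all
have at least one embedding in the same molecule. The canonical use of
a multi-pattern unit is pairing a stereochemistry-bearing pattern with
an atom-list-bearing pattern: SMARTS atom lists break R/S priority
assignment, so the two constraints are written as separate patterns and
AND-ed. The full truth value of a definition is::

    (allowed_1 OR allowed_2 OR ...) AND NOT (forbidden_1 OR forbidden_2 OR ...)

A definition with no allowed units is *abstract*: it never matches a
molecule directly and the class is populated through its structurally
defined descendants.

Text dialect (see FORMAT.md): one unit per line, a leading ``!`` marks
a forbidden unit, and `` & `` separates the AND-ed patterns of one unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem

from .errors import DefinitionError

#: separator between AND-ed SMARTS patterns inside one logic line
AND_SEPARATOR = " & "
#: line prefix marking a forbidden (NOT) unit
FORBIDDEN_PREFIX = "!"

_MAX_EMBEDDINGS = 64


def _compile_smarts(pattern: str, *, term: Optional[str] = None) -> Chem.Mol:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise DefinitionError(
            f"invalid SMARTS pattern {pattern!r}", term=term, pattern=pattern
        )
    return query


def _query_needs_explicit_h(query: Chem.Mol) -> bool:
    # Patterns that name hydrogen atoms explicitly (e.g. the printed
    # hydrogen-complete sugar strings) can only embed in a molecule whose
    # hydrogens are real graph atoms.
    return any(atom.GetAtomicNum() == 1 for atom in query.GetAtoms())


class Target:
    """A molecule prepared for matching; caches the hydrogen-explicit copy."""

    __slots__ = ("mol", "_mol_h")

    def __init__(self, mol: Chem.Mol):
        self.mol = mol
        self._mol_h = None

    @property
    def mol_h(self) -> Chem.Mol:
        if self._mol_h is None:
            self._mol_h = Chem.AddHs(self.mol)
        return self._mol_h


@dataclass(frozen=True)
class MatchUnit:
    """A conjunction of SMARTS patterns that must all embed in a molecule."""

    patterns: tuple[str, ...]
    term: Optional[str] = None

    def __post_init__(self):
        if not self.patterns:
            raise DefinitionError("a match unit needs at least one pattern",
                                  term=self.term)
        queries = tuple(_compile_smarts(p, term=self.term) for p in self.patterns)
        object.__setattr__(self, "_queries", queries)
        object.__setattr__(
            self, "_needs_h", tuple(_query_needs_explicit_h(q) for q in queries)
        )

    def _target_for(self, target: Target, i: int) -> Chem.Mol:
        return target.mol_h if self._needs_h[i] else target.mol

    def matches(self, target: Target) -> bool:
        return all(
            self._target_for(target, i).HasSubstructMatch(q, useChirality=True)
            for i, q in enumerate(self._queries)
        )

    def embeddings(self, target: Target) -> list[list[tuple[int, ...]]]:
        """Per-pattern lists of matched atom-index tuples."""
        return [
            [
                tuple(m)
                for m in self._target_for(target, i).GetSubstructMatches(
                    q, useChirality=True, maxMatches=_MAX_EMBEDDINGS
                )
            ]
            for i, q in enumerate(self._queries)
        ]

    def to_line(self, forbidden: bool = False) -> str:
        line = AND_SEPARATOR.join(self.patterns)
        return FORBIDDEN_PREFIX + line if forbidden else line


@dataclass(frozen=True)
class ClassDefinition:
    """OR-set of allowed units AND NOT OR-set of forbidden units."""

    allowed: tuple[MatchUnit, ...] = ()
    forbidden: tuple[MatchUnit, ...] = ()

    @property
    def is_abstract(self) -> bool:
        return not self.allowed

    def to_lines(self) -> list[str]:
        return [u.to_line() for u in self.allowed] + [
            u.to_line(forbidden=True) for u in self.forbidden
        ]


@dataclass(frozen=True)
class CompoundDefinition:
    """OR-set of full connection tables identifying a single compound.

    A molecule belongs to the compound class iff its structure key
    (standard InChI of the normalized structure) equals the key of at
    least one representation. Tautomers, microspecies and ring/chain
    forms of one compound are written as separate representations.
    """

    representations: tuple[str, ...]
    term: Optional[str] = None

    def __post_init__(self):
        if not self.representations:
            raise DefinitionError(
                "a compound definition needs at least one representation",
                term=self.term,
            )
        for smi in self.representations:
            if Chem.MolFromSmiles(smi) is None:
                raise DefinitionError(
                    f"representation SMILES does not parse: {smi!r}",
                    term=self.term, pattern=smi,
                )
        object.__setattr__(self, "_keys", None)

    @property
    def keys(self) -> frozenset[str]:
        """Structure keys of all representations (computed lazily)."""
        if self.__dict__.get("_keys") is None:
            from .chem import normalize, structure_key

            keys = frozenset(
                structure_key(normalize(Chem.MolFromSmiles(smi)))
                for smi in self.representations
            )
            object.__setattr__(self, "_keys", keys)
        return self.__dict__["_keys"]

    def matches_key(self, key: str) -> bool:
        return key in self.keys


@dataclass(frozen=True)
class MatchResult:
    """Outcome of evaluating a :class:`ClassDefinition` with explanation data.

    ``atom_embeddings`` holds, for every pattern of the reported unit
    (the violating forbidden unit if one fired, else the triggering
    allowed unit), the list of matched atom-index tuples.
    """

    matched: bool
    triggering_allowed_unit: Optional[int] = None
    violating_forbidden_unit: Optional[int] = None
    atom_embeddings: tuple = field(default=())


def parse_logic_lines(lines: Sequence[str], *, term: Optional[str] = None):
    """Split raw logic lines into (allowed_units, forbidden_units) pattern lists."""
    allowed, forbidden = [], []
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(FORBIDDEN_PREFIX):
            forbidden.append(line[len(FORBIDDEN_PREFIX):].strip())
        else:
            allowed.append(line)
    return allowed, forbidden


def compile_definition(
    allowed_lines: Sequence[str],
    forbidden_lines: Sequence[str],
    *,
    term: Optional[str] = None,
) -> ClassDefinition:
    """Compile raw logic lines (one unit per line) into a :class:`ClassDefinition`.

    Each line holds the patterns of one unit joined by `` & ``. Invalid
    SMARTS raises :class:`~ontoclass.errors.DefinitionError` naming the
    class and the offending pattern; it is never a silent non-match.
    """

    def build(lines):
        units = []
        for line in lines:
            patterns = tuple(p.strip() for p in line.split(AND_SEPARATOR))
            patterns = tuple(p for p in patterns if p)
            units.append(MatchUnit(patterns, term=term))
        return tuple(units)

    return ClassDefinition(allowed=build(allowed_lines),
                           forbidden=build(forbidden_lines))


def evaluate_class(molecule: Chem.Mol, definition: ClassDefinition) -> MatchResult:
    """Evaluate the boolean formula of ``definition`` against ``molecule``.

    The molecule must already be parsed and normalized. An abstract
    definition (no allowed units) matches nothing directly.
    """
    target = molecule if isinstance(molecule, Target) else Target(molecule)

    triggering = None
    for i, unit in enumerate(definition.allowed):
        if unit.matches(target):
            triggering = i
            break

    violating = None
    for i, unit in enumerate(definition.forbidden):
        if unit.matches(target):
            violating = i
            break

    matched = triggering is not None and violating is None
    if violating is not None:
        embeddings = tuple(definition.forbidden[violating].embeddings(target))
    elif triggering is not None:
        embeddings = tuple(definition.allowed[triggering].embeddings(target))
    else:
        embeddings = ()
    return MatchResult(
        matched=matched,
        triggering_allowed_unit=triggering,
        violating_forbidden_unit=violating,
        atom_embeddings=embeddings,
    )


def evaluate_compound(molecule: Chem.Mol, definition: CompoundDefinition) -> bool:
    """True iff the molecule is structurally identical to a representation.

    Identity is judged by the structure key (standard InChI) after the
    same normalization pipeline used on the representations, so the
    stereochemistry layer distinguishes enantiomers while input atom
    ordering and hydrogen notation are irrelevant.
    """
    from .chem import normalize, structure_key

    key = structure_key(normalize(molecule))
    return definition.matches_key(key)
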
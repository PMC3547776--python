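"""The is_a DAG ontology model and its OBO-dialect reader/writer.

The ontology is a set of named class terms connected by directed,
transitive ``is_a`` edges (child -> parent). A term may carry a
structural definition: either boolean SMARTS class logic or an OR-set
of exact compound representations; terms without one are abstract and
are populated through their descendants.

Serialization uses OBO 1.2 flat files with three dialect tags
(documented bit-exact in FORMAT.md):

``oc_smarts``
    one logic line per tag: a match unit, ``!``-prefixed if forbidden,
    `` & ``-joined if it AND-s several patterns.
``oc_smiles``
    one compound representation per tag.
``oc_scope``
    ``narrow`` (default) or ``broad`` per the two principal compound
    class types (intact defining group vs chemically modified
    derivatives).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
from rdkit import Chem

from .errors import (DefinitionError, OboParseError, ReasoningError,
                     UnknownTermError)
from .logic import (ClassDefinition, CompoundDefinition, MatchResult, Target,
                    compile_definition, evaluate_class, parse_logic_lines)

Definition = Union[ClassDefinition, CompoundDefinition]

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<rest>.*)$')

#: serialization order of the known term tags
_TAG_ORDER = ("id", "name", "synonym", "oc_scope", "oc_smarts", "oc_smiles",
              "is_a")


@dataclass
class ClassNode:
    """One ontology term."""

    id: str
    name: str = ""
    synonyms: list[str] = field(default_factory=list)
    definition: Optional[Definition] = None
    scope: str = "narrow"
    parents: list[str] = field(default_factory=list)
    #: unknown tags preserved verbatim as (tag, value) pairs
    annotations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_abstract(self) -> bool:
        if self.definition is None:
            return True
        if isinstance(self.definition, ClassDefinition):
            return self.definition.is_abstract
        return False

    def _content(self):
        if isinstance(self.definition, ClassDefinition):
            d = ("class",
                 tuple(u.patterns for u in self.definition.allowed),
                 tuple(u.patterns for u in self.definition.forbidden))
        elif isinstance(self.definition, CompoundDefinition):
            d = ("compound", self.definition.representations)
        else:
            d = None
        return (self.id, self.name, tuple(self.synonyms), d, self.scope,
                tuple(sorted(self.parents)), tuple(self.annotations))

    def __eq__(self, other):
        return isinstance(other, ClassNode) and self._content() == other._content()


class EffectiveDefinition:
    """Rule-4 composite: a node's own definition AND every ancestor's.

    Only class logic is inherited: an abstract ancestor imposes nothing,
    and an ancestor defined as an exact compound imposes nothing on its
    descendants either (a stereo-defined child compound under its
    stereo-undefined parent compound could never satisfy the parent's
    exact identity). The node's own definition, of either kind, is
    always a member.
    """

    def __init__(self, term_id: str, members: list[tuple[str, Definition]]):
        self.term_id = term_id
        self.members = tuple(sorted(members, key=lambda m: m[0]))

    def satisfied_by(self, molecule, *, key: Optional[str] = None) -> bool:
        """True iff the molecule satisfies every member definition.

        With no members (fully abstract chain) nothing satisfies the
        composite directly. ``key`` may pass a precomputed structure key
        to avoid recomputing InChI for compound members.
        """
        if not self.members:
            return False
        target = molecule if isinstance(molecule, Target) else Target(molecule)
        for _, definition in self.members:
            if isinstance(definition, CompoundDefinition):
                if key is None:
                    from .chem import normalize, structure_key
                    key = structure_key(normalize(target.mol))
                if not definition.matches_key(key):
                    return False
            else:
                if definition.is_abstract or not evaluate_class(target, definition).matched:
                    return False
        return True

    def explain(self, molecule) -> dict[str, MatchResult]:
        """Per-member match results for the class-logic members."""
        target = molecule if isinstance(molecule, Target) else Target(molecule)
        return {
            term: evaluate_class(target, definition)
            for term, definition in self.members
            if isinstance(definition, ClassDefinition)
        }


class ChemOntology:
    """Directed acyclic is_a graph of :class:`ClassNode` terms."""

    def __init__(self, nodes: Iterable[ClassNode] = (),
                 header: Optional[list[tuple[str, str]]] = None):
        self.nodes: dict[str, ClassNode] = {}
        self.header: list[tuple[str, str]] = header or [("format-version", "1.2")]
        self._graph: Optional[nx.DiGraph] = None
        for node in nodes:
            self.add_node(node)

    # -- construction -------------------------------------------------
    def add_node(self, node: ClassNode) -> None:
        if node.id in self.nodes:
            raise OboParseError(f"duplicate term id {node.id!r}")
        self.nodes[node.id] = node
        self._graph = None

    def add_edge(self, child: str, parent: str) -> None:
        self._require(child)
        self._require(parent)
        if parent not in self.nodes[child].parents:
            self.nodes[child].parents.append(parent)
            self._graph = None

    def _require(self, term_id: str) -> ClassNode:
        try:
            return self.nodes[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term id {term_id!r}") from None

    # -- graph views --------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        """child -> parent digraph over all declared terms."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.nodes)
            for node in self.nodes.values():
                for parent in node.parents:
                    g.add_edge(node.id, parent)
            self._graph = g
        return self._graph

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive is_a closure of a term, excluding the term itself."""
        self._require(term_id)
        return set(nx.descendants(self.graph, term_id))

    def descendants(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(nx.ancestors(self.graph, term_id))

    def roots(self) -> list[str]:
        return sorted(n for n, node in self.nodes.items() if not node.parents)

    def depth(self) -> int:
        """Longest root-to-leaf path length (levels) of the DAG."""
        if not self.nodes:
            return 0
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ReasoningError("ontology graph contains a cycle")
        return nx.dag_longest_path_length(self.graph) + 1

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.nodes

    def __iter__(self):
        return iter(self.nodes.values())

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other):
        return (isinstance(other, ChemOntology)
                and set(self.nodes) == set(other.nodes)
                and all(self.nodes[i] == other.nodes[i] for i in self.nodes))

    # -- reasoning-facing ---------------------------------------------
    def effective_definition(self, term_id: str) -> EffectiveDefinition:
        """Composite constraint of a term and all its ancestors (Rule 4)."""
        node = self._require(term_id)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ReasoningError("ontology graph contains a cycle")
        members: list[tuple[str, Definition]] = []
        if node.definition is not None and not (
            isinstance(node.definition, ClassDefinition)
            and node.definition.is_abstract
        ):
            members.append((term_id, node.definition))
        for anc in self.ancestors(term_id):
            d = self.nodes[anc].definition
            if isinstance(d, ClassDefinition) and not d.is_abstract:
                members.append((anc, d))
        return EffectiveDefinition(term_id, members)


# ---------------------------------------------------------------------------
# OBO reading / writing


def _parse_synonym(value: str) -> str:
    m = _SYNONYM_RE.match(value.strip())
    if not m:
        return value.strip()
    return m.group("text").replace('\\"', '"')


def _strip_obo_comment(value: str) -> str:
    # only used for tags whose values cannot contain '!', such as is_a
    return value.split("!", 1)[0].strip()


def parse_obo(source) -> ChemOntology:
    """Parse an OBO 1.2 stream (path, string content or file-like).

    ``oc_smarts`` lines are compiled into class logic, ``oc_smiles``
    lines into compound definitions; ``is_a`` lines become edges.
    Unknown tags are preserved as opaque annotations. Duplicate ids,
    references to undeclared terms, a term carrying both definition
    kinds, and invalid SMARTS are errors (with term id and line number).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        p = Path(str(source))
        if "\n" not in str(source) and p.exists():
            text = p.read_text()
        else:
            text = str(source)

    header: list[tuple[str, str]] = []
    ontology = None
    stanza = None          # list of (lineno, tag, value) of current [Term]
    other_stanza = False   # inside a non-Term stanza (ignored content)
    terms: list[list[tuple[int, str, str]]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("["):
            if stripped == "[Term]":
                stanza = []
                terms.append(stanza)
                other_stanza = False
            else:
                stanza = None
                other_stanza = True
            continue
        if ":" not in stripped:
            raise OboParseError(f"malformed line: {stripped!r}", line=lineno)
        tag, value = stripped.split(":", 1)
        tag, value = tag.strip(), value.strip()
        if stanza is not None:
            stanza.append((lineno, tag, value))
        elif not other_stanza:
            header.append((tag, value))

    if not any(tag == "format-version" for tag, _ in header):
        header.insert(0, ("format-version", "1.2"))
    ontology = ChemOntology(header=header)

    pending_edges: list[tuple[str, str, int]] = []
    for stanza in terms:
        node = ClassNode(id="")
        smarts_lines: list[str] = []
        smiles_lines: list[str] = []
        first_line = stanza[0][0] if stanza else 0
        for lineno, tag, value in stanza:
            if tag == "id":
                node.id = value
            elif tag == "name":
                node.name = value
            elif tag == "synonym":
                node.synonyms.append(_parse_synonym(value))
            elif tag == "is_a":
                pending_edges.append((node.id, _strip_obo_comment(value), lineno))
            elif tag == "oc_scope":
                if value not in ("narrow", "broad"):
                    raise OboParseError(
                        f"oc_scope must be narrow|broad, got {value!r}",
                        line=lineno)
                node.scope = value
            elif tag == "oc_smarts":
                smarts_lines.append((lineno, value))
            elif tag == "oc_smiles":
                smiles_lines.append((lineno, value))
            else:
                node.annotations.append((tag, value))
        if not node.id:
            raise OboParseError("term stanza without id", line=first_line)
        if smarts_lines and smiles_lines:
            raise OboParseError(
                f"term {node.id!r} carries both oc_smarts and oc_smiles",
                line=first_line)
        if smarts_lines:
            allowed, forbidden = parse_logic_lines(
                [v for _, v in smarts_lines], term=node.id)
            try:
                node.definition = compile_definition(
                    allowed, forbidden, term=node.id)
            except DefinitionError as exc:
                raise DefinitionError(
                    str(exc), term=node.id, pattern=exc.pattern,
                    line=smarts_lines[0][0]) from exc
        elif smiles_lines:
            node.definition = CompoundDefinition(
                tuple(v for _, v in smiles_lines), term=node.id)
        ontology.add_node(node)

    missing = sorted({p for _, p, _ in pending_edges} - set(ontology.nodes))
    if missing:
        raise OboParseError(
            "is_a references undeclared term(s): " + ", ".join(missing))
    for child, parent, _ in pending_edges:
        ontology.add_edge(child, parent)
    return ontology


def serialize_obo(ontology: ChemOntology, stream=None) -> str:
    """Write the ontology deterministically: terms sorted by id, tags in
    fixed order. ``parse_obo(serialize_obo(o))`` structurally equals ``o``."""
    out = io.StringIO()
    for tag, value in ontology.header:
        out.write(f"{tag}: {value}\n")
    for term_id in sorted(ontology.nodes):
        node = ontology.nodes[term_id]
        out.write("\n[Term]\n")
        out.write(f"id: {node.id}\n")
        if node.name:
            out.write(f"name: {node.name}\n")
        for syn in node.synonyms:
            quoted = syn.replace('"', '\\"')
            out.write(f'synonym: "{quoted}" EXACT []\n')
        out.write(f"oc_scope: {node.scope}\n")
        if isinstance(node.definition, ClassDefinition):
            for line in node.definition.to_lines():
                out.write(f"oc_smarts: {line}\n")
        elif isinstance(node.definition, CompoundDefinition):
            for rep in node.definition.representations:
                out.write(f"oc_smiles: {rep}\n")
        for parent in sorted(node.parents):
            pname = ontology.nodes[parent].name if parent in ontology.nodes else ""
            comment = f" ! {pname}" if pname else ""
            out.write(f"is_a: {parent}{comment}\n")
        for tag, value in node.annotations:
            out.write(f"{tag}: {value}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def ancestors(ontology: ChemOntology, term_id: str) -> set[str]:
    """Module-level convenience wrapper around :meth:`ChemOntology.ancestors`."""
    return ontology.ancestors(term_id)


def effective_definition(ontology: ChemOntology, term_id: str) -> EffectiveDefinition:
    return ontology.effective_definition(term_id)
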
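"""Chemistry-aware ontology validation.

Two layers of checks:

* structural graph checks — is_a cycles (a term must never become an
  ancestor of itself) and redundant edges (an is_a edge whose target is
  already reachable through another path, i.e. a transitive-reduction
  violation);
* chemical consistency checks — probe molecules are evaluated against
  every structurally defined term; whenever a probe satisfies a term's
  own definition but fails the class logic of one of its ancestors, the
  hierarchy and the definitions disagree and the pair is reported.
  Representations of exact-compound terms are checked against their own
  ancestors' class logic the same way.

Deciding SMARTS subsumption symbolically is intractable in general, so
consistency is probe-based: the guarantee extends exactly to the probe
pool supplied by the ontology author.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
from rdkit import Chem

from .errors import ReasoningError
from .logic import (ClassDefinition, CompoundDefinition, Target,
                    evaluate_class)
from .ontology import ChemOntology


@dataclass
class LintReport:
    cycles: list[list[str]] = field(default_factory=list)
    redundant_edges: list[tuple[str, str]] = field(default_factory=list)
    inconsistent_nodes: list[tuple[str, str, str]] = field(default_factory=list)
    invalid_patterns: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (self.cycles or self.redundant_edges
                    or self.inconsistent_nodes or self.invalid_patterns)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cycles": self.cycles,
                "redundant_edges": [list(e) for e in self.redundant_edges],
                "inconsistent_nodes": [list(v) for v in self.inconsistent_nodes],
                "invalid_patterns": [list(v) for v in self.invalid_patterns],
                "clean": self.is_clean,
            },
            indent=2,
        )

    def summary_lines(self) -> list[str]:
        lines = []
        for cyc in self.cycles:
            lines.append("cycle: " + " -> ".join(cyc))
        for child, parent in self.redundant_edges:
            lines.append(f"redundant edge: {child} is_a {parent}")
        for node, probe, anc in self.inconsistent_nodes:
            lines.append(
                f"inconsistent: probe {probe} satisfies {node} "
                f"but fails ancestor {anc}")
        for node, pattern in self.invalid_patterns:
            lines.append(f"invalid pattern in {node}: {pattern}")
        if not lines:
            lines.append("ontology is clean")
        return lines


def find_cycles(ontology: ChemOntology) -> list[list[str]]:
    """Every elementary is_a cycle, reported once as a closed id path.

    Each cycle is rotated to start (and end) at its lexicographically
    smallest member, e.g. ``[A, B, A]``; a self-loop is ``[A, A]``.
    """
    out = []
    for cycle in nx.simple_cycles(ontology.graph):
        k = cycle.index(min(cycle))
        rotated = cycle[k:] + cycle[:k]
        out.append(rotated + [rotated[0]])
    return sorted(out)


def find_redundant_edges(ontology: ChemOntology) -> list[tuple[str, str]]:
    """Edges (child, parent) where parent is reachable from child via
    another path. Requires an acyclic graph."""
    g = ontology.graph
    if not nx.is_directed_acyclic_graph(g):
        raise ReasoningError(
            "redundant-edge analysis requires an acyclic ontology")
    reduced = nx.transitive_reduction(g)
    return sorted(set(g.edges()) - set(reduced.edges()))


def _own_match(node_def, target: Target, key_getter) -> bool:
    if isinstance(node_def, ClassDefinition):
        return (not node_def.is_abstract
                and evaluate_class(target, node_def).matched)
    if isinstance(node_def, CompoundDefinition):
        return node_def.matches_key(key_getter())
    return False


def check_consistency(
    ontology: ChemOntology,
    probes: Iterable,
) -> list[tuple[str, str, str]]:
    """Probe-based child/ancestor agreement check.

    ``probes`` yields rdkit molecules or SMILES strings (assumed
    normalized). For every probe satisfying a defined term's own
    definition, any ancestor class logic the probe fails is reported as
    ``(term_id, probe_smiles, ancestor_id)``. Additionally, every
    representation of an exact-compound term is checked against that
    term's own ancestors' class logic.
    """
    from .chem import normalize, structure_key

    violations: list[tuple[str, str, str]] = []

    class_defs = {
        n.id: n.definition for n in ontology
        if isinstance(n.definition, ClassDefinition)
        and not n.definition.is_abstract
    }

    def ancestor_failures(term_id: str, target: Target) -> list[str]:
        failing = []
        for anc in sorted(ontology.ancestors(term_id)):
            d = class_defs.get(anc)
            if d is not None and not evaluate_class(target, d).matched:
                failing.append(anc)
        return failing

    for probe in probes:
        mol = Chem.MolFromSmiles(probe) if isinstance(probe, str) else probe
        if mol is None:
            continue
        target = Target(mol)
        smiles = Chem.MolToSmiles(mol)
        key_cache: list[Optional[str]] = [None]

        def key_getter():
            if key_cache[0] is None:
                key_cache[0] = structure_key(normalize(target.mol))
            return key_cache[0]

        for node in ontology:
            if node.definition is None:
                continue
            if _own_match(node.definition, target, key_getter):
                for anc in ancestor_failures(node.id, target):
                    violations.append((node.id, smiles, anc))

    # compound representations vs their own ancestor class logic
    for node in ontology:
        if not isinstance(node.definition, CompoundDefinition):
            continue
        for rep in node.definition.representations:
            mol = Chem.MolFromSmiles(rep)
            if mol is None:
                continue
            target = Target(normalize(mol))
            for anc in ancestor_failures(node.id, target):
                violations.append((node.id, rep, anc))

    return sorted(set(violations))


def validate(
    ontology: ChemOntology,
    probes: Sequence = (),
) -> LintReport:
    """Run every implemented check and collect a :class:`LintReport`.

    The report is empty iff the ontology passes all checks. Redundancy
    and consistency are skipped (not silently passed) when cycles make
    them undefined — the cycle findings themselves keep the report
    non-empty in that case.
    """
    report = LintReport()
    report.cycles = find_cycles(ontology)
    if not report.cycles:
        report.redundant_edges = find_redundant_edges(ontology)
        report.inconsistent_nodes = check_consistency(ontology, probes)
    return report
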
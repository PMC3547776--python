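"""Automated assignment of compounds to ontology classes.

A compound is assigned to a structurally defined term when it satisfies
the term's own definition *and* the class logic of every ancestor in
the is_a chain (Rule-4 gating: the child inherits all parent SMARTS
definitions AND-ed). Abstract terms are never matched directly; they
enter a compound's class set only as ancestors of assigned terms. For
reporting, the deepest matching node of every path is kept: the set of
assigned classes with no assigned descendant — an antichain that may
span several branches, because a single compound legitimately belongs
to many concurrent categories.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdkit import Chem

from .chem import (NormalizationConfig, StructureRecord, is_mixture,
                   normalize, structure_key)
from .errors import OntoclassError, ReasoningError
from .logic import ClassDefinition, CompoundDefinition, Target, evaluate_class
from .ontology import ChemOntology

import networkx as nx

logger = logging.getLogger(__name__)

_PROGRESS_EVERY = 1000


@dataclass
class AnnotationRecord:
    """One input structure with its class assignments and explanation data."""

    source_id: str
    smiles: str = ""
    all_classes: frozenset[str] = frozenset()
    deepest_classes: frozenset[str] = frozenset()
    direct_classes: frozenset[str] = frozenset()
    mixture_flag: bool = False
    error: Optional[str] = None


@dataclass
class BatchSummary:
    """Per-class deepest-assignment frequencies plus batch bookkeeping.

    Both assignment counts of a compound are of interest — the terms it
    matched directly and the full ancestor closure — so the summary
    carries averages of both.
    """

    deepest_counts: Counter = field(default_factory=Counter)
    n_records: int = 0
    n_classified: int = 0
    n_errors: int = 0
    n_mixtures: int = 0
    n_skipped_mixtures: int = 0
    mean_direct_classes: float = 0.0
    mean_all_classes: float = 0.0


@dataclass
class ClassifyConfig:
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    skip_mixtures: bool = False
    deepest_only: bool = False


def _own_matches(molecule, ontology: ChemOntology) -> dict[str, bool]:
    """Own-definition truth value for every structurally defined term."""
    target = molecule if isinstance(molecule, Target) else Target(molecule)
    key: Optional[str] = None
    out: dict[str, bool] = {}
    for node in ontology:
        d = node.definition
        if isinstance(d, ClassDefinition) and not d.is_abstract:
            out[node.id] = evaluate_class(target, d).matched
        elif isinstance(d, CompoundDefinition):
            if key is None:
                key = structure_key(target.mol)
            out[node.id] = d.matches_key(key)
    return out


def classify(molecule, ontology: ChemOntology) -> set[str]:
    """Ids of every term whose Rule-4 composite the normalized molecule
    satisfies, closed under ancestry.

    Ancestor gating uses class logic only; ancestor exact-compound
    definitions impose nothing on descendants.
    """
    if not nx.is_directed_acyclic_graph(ontology.graph):
        raise ReasoningError("classification requires an acyclic ontology")
    own = _own_matches(molecule, ontology)
    class_logic_ids = {
        tid for tid in own
        if isinstance(ontology.nodes[tid].definition, ClassDefinition)
    }
    assigned: set[str] = set()
    for tid, hit in own.items():
        if not hit:
            continue
        ancs = ontology.ancestors(tid)
        if all(own[a] for a in ancs if a in class_logic_ids):
            assigned.add(tid)
            assigned |= ancs
    return assigned


def direct_classes(molecule, ontology: ChemOntology) -> set[str]:
    """Terms assigned by their own composite, before ancestor closure."""
    own = _own_matches(molecule, ontology)
    class_logic_ids = {
        tid for tid in own
        if isinstance(ontology.nodes[tid].definition, ClassDefinition)
    }
    return {
        tid for tid, hit in own.items()
        if hit and all(own[a] for a in ontology.ancestors(tid)
                       if a in class_logic_ids)
    }


def deepest(assignments: set[str], ontology: ChemOntology) -> set[str]:
    """Members of an ancestor-closed assignment set with no assigned
    descendant: the deepest matching node of every path."""
    return {
        c for c in assignments
        if not any(c in ontology.ancestors(d) for d in assignments if d != c)
    }


def annotate(record: StructureRecord, ontology: ChemOntology,
             config: Optional[ClassifyConfig] = None) -> AnnotationRecord:
    """Classify one structure record; failures are carried on the record."""
    config = config or ClassifyConfig()
    if record.molecule is None:
        return AnnotationRecord(source_id=record.source_id,
                                error=record.error or "unparseable structure")
    try:
        mol = normalize(record.molecule, config.normalization)
    except OntoclassError as exc:
        return AnnotationRecord(source_id=record.source_id, error=str(exc))
    mixture = is_mixture(mol)
    smiles = Chem.MolToSmiles(mol)
    if mixture and config.skip_mixtures:
        return AnnotationRecord(source_id=record.source_id, smiles=smiles,
                                mixture_flag=True, error="skipped: mixture")
    try:
        all_ids = classify(mol, ontology)
        direct = direct_classes(mol, ontology)
    except OntoclassError as exc:
        return AnnotationRecord(source_id=record.source_id, smiles=smiles,
                                mixture_flag=mixture, error=str(exc))
    return AnnotationRecord(
        source_id=record.source_id,
        smiles=smiles,
        all_classes=frozenset(all_ids),
        deepest_classes=frozenset(deepest(all_ids, ontology)),
        direct_classes=frozenset(direct),
        mixture_flag=mixture,
    )


def classify_batch(
    structures: Iterable[StructureRecord],
    ontology: ChemOntology,
    config: Optional[ClassifyConfig] = None,
) -> tuple[list[AnnotationRecord], BatchSummary]:
    """Annotate a stream of structures; per-record errors never abort
    the batch. Returns the records (input order) and a summary whose
    per-class frequencies count deepest assignments only."""
    config = config or ClassifyConfig()
    records: list[AnnotationRecord] = []
    summary = BatchSummary()
    direct_total = 0
    all_total = 0
    for rec in structures:
        ann = annotate(rec, ontology, config)
        records.append(ann)
        summary.n_records += 1
        if ann.error is not None:
            summary.n_errors += 1
            if ann.error.startswith("skipped"):
                summary.n_skipped_mixtures += 1
        else:
            summary.n_classified += 1
            direct_total += len(ann.direct_classes)
            all_total += len(ann.all_classes)
            for cid in ann.deepest_classes:
                summary.deepest_counts[cid] += 1
        if ann.mixture_flag:
            summary.n_mixtures += 1
        if summary.n_records % _PROGRESS_EVERY == 0:
            logger.info("classified %d records", summary.n_records)
    if summary.n_classified:
        summary.mean_direct_classes = direct_total / summary.n_classified
        summary.mean_all_classes = all_total / summary.n_classified
    return records, summary


# ---------------------------------------------------------------------------
# tabular output

ANNOTATION_COLUMNS = ("source_id", "smiles", "deepest_classes", "all_classes",
                      "mixture_flag", "error")


def annotation_rows(records: Iterable[AnnotationRecord],
                    deepest_only: bool = False):
    yield "\t".join(ANNOTATION_COLUMNS)
    for r in records:
        all_col = "" if deepest_only else "|".join(sorted(r.all_classes))
        yield "\t".join([
            r.source_id,
            r.smiles,
            "|".join(sorted(r.deepest_classes)),
            all_col,
            "1" if r.mixture_flag else "0",
            r.error or "",
        ])


def summary_rows(summary: BatchSummary, ontology: ChemOntology):
    yield "\t".join(("class_id", "class_name", "deepest_count"))
    for cid in sorted(summary.deepest_counts):
        name = ontology.nodes[cid].name if cid in ontology else ""
        yield "\t".join((cid, name, str(summary.deepest_counts[cid])))
    yield f"# records\t\t{summary.n_records}"
    yield f"# classified\t\t{summary.n_classified}"
    yield f"# errors\t\t{summary.n_errors}"
    yield f"# mixtures\t\t{summary.n_mixtures}"
    yield f"# mean_direct_classes\t\t{summary.mean_direct_classes:.3f}"
    yield f"# mean_all_classes\t\t{summary.mean_all_classes:.3f}"
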
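"""Cue-word mining of chemical class-term candidates from free text.

Chemists coin class terms from compound names with a handful of
characteristic expressions: "imidazole *derivatives*", "androstane
*scaffold*", "*substituted* pyridines". Scanning text for these cue
words and capturing the adjacent token yields a ranked candidate list
of class terms worth defining structurally in the ontology.

The capture window is one token by default (hyphenated tokens kept
whole); multi-word chemical names are beyond this heuristic, though the
window is configurable for experimentation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: suffix cues: the class term precedes the cue word
SUFFIX_CUES = frozenset([
    "analogue", "analogues", "analog", "analogs",
    "derivative", "derivatives",
    "scaffold", "scaffolds",
    "skeleton", "skeletons",
    "backbone", "backbones",
])
#: prefix cues: the class term follows the cue word
PREFIX_CUES = frozenset(["substituted"])

_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9\-']*")


@dataclass
class TermCandidate:
    term: str
    frequency: int = 0
    cues_seen: set[str] = field(default_factory=set)


def _tokenize(text: str) -> list[str]:
    return [t.lower() for t in _TOKEN_RE.findall(text)]


def extract_candidates(
    text: str,
    suffix_cues=None,
    prefix_cues=None,
    window: int = 1,
) -> list[TermCandidate]:
    """Extract and rank class-term candidates adjacent to cue words.

    For every suffix-cue occurrence the preceding ``window`` token(s)
    are captured, for every prefix-cue occurrence the following one(s);
    captures that are themselves cue words, or that contain no letter,
    are discarded. Candidates are aggregated and sorted by frequency
    descending, ties broken lexicographically — a total, deterministic
    order.
    """
    suffix_cues = frozenset(suffix_cues) if suffix_cues is not None else SUFFIX_CUES
    prefix_cues = frozenset(prefix_cues) if prefix_cues is not None else PREFIX_CUES
    all_cues = suffix_cues | prefix_cues
    tokens = _tokenize(text)

    found: dict[str, TermCandidate] = {}

    def capture(span: list[str], cue: str) -> None:
        term = " ".join(span)
        if not term or term in all_cues:
            return
        if not any(c.isalpha() for c in term):
            return
        cand = found.setdefault(term, TermCandidate(term))
        cand.frequency += 1
        cand.cues_seen.add(cue)

    for i, tok in enumerate(tokens):
        if tok in suffix_cues and i >= window:
            span = tokens[i - window:i]
            if not any(t in all_cues for t in span):
                capture(span, tok)
        if tok in prefix_cues and i + window < len(tokens):
            span = tokens[i + 1:i + 1 + window]
            if not any(t in all_cues for t in span):
                capture(span, tok)

    return sorted(found.values(), key=lambda c: (-c.frequency, c.term))


def candidate_rows(candidates):
    yield "term\tfrequency\tcues"
    for c in candidates:
        yield f"{c.term}\t{c.frequency}\t{'|'.join(sorted(c.cues_seen))}"
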
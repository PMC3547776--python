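"""Exception hierarchy shared by all ontoclass modules."""


class OntoclassError(Exception):
    """Base class for all errors raised by this package."""


class DefinitionError(OntoclassError):
    """A class or compound structure definition is malformed.

    Raised when a SMARTS pattern does not compile or a compound
    representation SMILES does not parse. Carries the offending pattern
    and, when known, the ontology term the definition belongs to.
    """

    def __init__(self, message, *, term=None, pattern=None, line=None):
        self.term = term
        self.pattern = pattern
        self.line = line
        prefix = []
        if term is not None:
            prefix.append(f"term {term!r}")
        if line is not None:
            prefix.append(f"line {line}")
        if prefix:
            message = f"[{', '.join(prefix)}] {message}"
        super().__init__(message)


class OboParseError(OntoclassError):
    """The OBO document violates the dialect (duplicate ids, dangling is_a, ...)."""

    def __init__(self, message, *, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ReasoningError(OntoclassError):
    """Ontology graph is not in a state the requested reasoning step supports
    (e.g. a cycle was found where a DAG is required)."""


class UnknownTermError(OntoclassError, KeyError):
    """A term id was looked up that does not exist in the ontology."""
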
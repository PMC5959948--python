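"""Exception hierarchy shared across the package."""


class PhenorankError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhenorankError):
    """A required column, path, root term, or parameter is missing/invalid."""


class EmptyInputError(PhenorankError):
    """An input file or collection contained no usable records."""


class OboParseError(PhenorankError):
    """The OBO file could not be parsed or violates ontology invariants."""


class DomainError(PhenorankError):
    """An identifier does not resolve, or an operation's precondition fails."""


class InputError(PhenorankError):
    """Malformed or inconsistent tabular input (e.g. duplicate sentence ids)."""


class InsufficientDataError(PhenorankError):
    """Too few records to run a statistical test."""
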
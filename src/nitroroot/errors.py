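"""Exception types shared across the pipeline stages."""


class NitrorootError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NitrorootError, ValueError):
    """A simulator or analysis configuration violates its invariants."""


class ParseError(NitrorootError, ValueError):
    """An input file could not be parsed; the message names file, line and column."""


class DesignError(NitrorootError, ValueError):
    """The factorial sample design is invalid (unbalanced, duplicated, r < 2)."""


class AnalysisError(NitrorootError, ValueError):
    """A computation is undefined for the given data (e.g. all genes trimmed)."""
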
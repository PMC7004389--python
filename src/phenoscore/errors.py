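"""Exception hierarchy.

``DataError`` covers malformed or inconsistent user inputs (exit code 2 in the
CLI); plain ``ValueError`` is reserved for programmer misuse of the API.
"""


class PhenoscoreError(Exception):
    """Base class for all package-specific errors."""


class DataError(PhenoscoreError):
    """Malformed or inconsistent input data."""


class OntologyError(DataError):
    """Structural problem in an ontology file (cycles, dangling edges, ...)."""


class UnknownTermError(DataError):
    """A term identifier could not be resolved in the ontology."""
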
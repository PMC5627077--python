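"""Exception hierarchy.

Exit-code convention for the CLI: 0 ok, 1 data error, 2 config error.
"""


class ShoalkitError(Exception):
    """Base class for all shoalkit errors."""

    exit_code = 1


class DataError(ShoalkitError):
    """Problem with the content of an input (values, balance, ranges)."""

    exit_code = 1


class ParseError(DataError):
    """A file could not be parsed under the declared dialect."""


class StructuralError(DataError):
    """A file parsed but its shape is inconsistent (e.g. varying fish count)."""


class BoundsError(DataError):
    """A requested frame window falls outside the trial."""


class ConfigError(ShoalkitError):
    """Invalid configuration (bad geometry, non-monotone bin edges, ...)."""

    exit_code = 2
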
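"""Exception hierarchy shared across the package.

Each error class maps to one CLI exit status so shell users can branch on
the failure mode (see :mod:`herdrank.cli`).
"""


class HerdrankError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(HerdrankError):
    """A required column is missing or the header cannot be interpreted."""

    exit_code = 3


class ParseError(HerdrankError):
    """A cell could not be parsed (bad timestamp, non-numeric duration)."""

    exit_code = 3


class ValidationError(HerdrankError):
    """Rows violate an invariant (t_out < t_in, actor == reactor, ...)."""

    exit_code = 3


class ParameterError(HerdrankError):
    """An argument is outside its domain (negative sec, k not in {2, 3})."""

    exit_code = 4
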
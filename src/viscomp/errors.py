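"""Exception hierarchy shared across the pipeline.

``ValidationError`` covers bad user inputs (malformed tables, impossible
designs, unknown configuration names); the CLI maps it to exit code 1.
Everything else propagates as a runtime error (exit code 2).
"""


class ViscompError(Exception):
    """Base class for all package errors."""


class ValidationError(ViscompError, ValueError):
    """Invalid input data or configuration supplied by the caller."""


class InvalidDesignError(ValidationError):
    """A comparison design that cannot be constructed (e.g. fewer than 2 items)."""


class LookupRatingError(ValidationError, KeyError):
    """An item referenced by a comparison is missing from a rating table."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return ValueError.__str__(self)


class UndefinedCorrelationError(ValidationError):
    """Correlation requested on a zero-variance input."""
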
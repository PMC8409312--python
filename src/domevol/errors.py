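"""Exception hierarchy shared across the package."""


class DomevolError(Exception):
    """Base class for all package errors."""


class FormatError(DomevolError):
    """A text input violates its dialect (bad field, bad vocabulary, bad row).

    Carries the offending line number when the parser knows it.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UniquenessError(DomevolError):
    """A key that must be unique (e.g. an organism code) appeared twice."""


class ContractError(DomevolError):
    """A caller violated an operation's precondition."""


class DataIntegrityError(DomevolError):
    """A referential-integrity violation while building the datastore."""


class FixtureSpecError(DomevolError):
    """A synthetic-cohort specification is infeasible."""
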
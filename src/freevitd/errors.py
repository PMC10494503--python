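"""Exception hierarchy.

All freevitd errors derive from :class:`FreeVitDError` so callers can catch
everything the package raises with a single except clause.  Subclasses map
onto the CLI exit codes: schema/config problems exit 2, computation problems
exit 3.
"""


class FreeVitDError(Exception):
    """Base class for all freevitd errors."""


class DomainError(FreeVitDError, ValueError):
    """A numeric input is outside the mathematically admissible domain
    (negative concentration, non-positive value under a log transform, ...)."""


class MissingInputError(FreeVitDError, KeyError):
    """A required variable is absent from a participant record."""

    def __init__(self, variable: str, context: str = ""):
        self.variable = variable
        msg = f"missing required variable {variable!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError would quote the whole message
        return self.args[0]


class SchemaError(FreeVitDError, ValueError):
    """A file (cohort CSV, equation spec) does not conform to the documented
    schema."""


class ConfigError(FreeVitDError, ValueError):
    """An invalid configuration object (bad frequencies, bad threshold, ...)."""


class InputError(FreeVitDError, ValueError):
    """Structurally invalid analysis input (length mismatch, too few rows)."""


class SingularDesignError(FreeVitDError, ValueError):
    """A regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )
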
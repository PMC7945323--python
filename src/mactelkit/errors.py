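"""Exception hierarchy shared across the toolkit.

All errors derive from :class:`MactelkitError` so callers can catch one
base class; most also derive from the matching builtin (``ValueError`` or
``RuntimeError``) to stay idiomatic.
"""


class MactelkitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MactelkitError, ValueError):
    """A simulation or pipeline configuration field is invalid.

    The message names the offending field.
    """


class SamplingError(MactelkitError, RuntimeError):
    """Case/control enrichment cannot be satisfied (e.g. prevalence too
    low to yield the requested case count from the simulated pool)."""


class DataError(MactelkitError, ValueError):
    """Input data violates a contract (all-missing SNP, fully missing
    phenotype table, ...)."""


class SchemaError(MactelkitError, ValueError):
    """A table is missing required columns/phenotypes; names are listed."""


class DimensionError(MactelkitError, ValueError):
    """Matrix dimensions disagree with the configuration."""


class DomainError(MactelkitError, ValueError):
    """A numeric argument is outside its mathematical domain
    (p-values outside [0, 1], empty p-value lists, ...)."""


class EmptyInstrumentError(MactelkitError, ValueError):
    """No instrument SNP overlaps the genotype panel after harmonisation."""


class DegenerateScoreError(MactelkitError, ValueError):
    """An allele-score column has zero variance and cannot be standardized."""


class FitError(MactelkitError, RuntimeError):
    """A regression fit failed (separation, non-convergence, rank
    deficiency); carries whatever diagnostics were available."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientInstrumentsError(MactelkitError, ValueError):
    """Fewer than three instruments: the Egger intercept test is undefined."""


class SparseTableError(MactelkitError, ValueError):
    """A 2x2 contingency table contains an empty cell; the Woolf
    standard error is undefined without a continuity correction."""
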
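"""Exception hierarchy for asepg.

All exceptions derive from :class:`AsepgError` so callers can catch the
package's failures with a single except clause; the finer classes separate
malformed input files, invalid values, exons that cannot be tested at all,
and misuse of the experiment drivers.
"""


class AsepgError(Exception):
    """Base class for all asepg errors."""


class TableFormatError(AsepgError, ValueError):
    """A delimited-text table is structurally malformed (e.g. missing column)."""


class ValidationError(AsepgError, ValueError):
    """A value violates a domain invariant (negative count, p-value > 1, ...)."""


class UntestableExonError(AsepgError):
    """The exon carries no usable reads, so no test or fit is defined.

    An untestable exon is reported as such -- never silently as balanced.
    """


class DomainError(AsepgError, ValueError):
    """A parameter is outside its mathematical domain (q not in (0,1), alpha <= 0)."""


class ExperimentMisuseError(AsepgError, ValueError):
    """An experiment driver was called with an incompatible configuration."""
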
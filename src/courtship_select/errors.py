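"""Exception hierarchy shared across the package.

Validation problems (bad labels, malformed trials, impossible values) raise
:class:`ValidationError`; structurally unreadable inputs raise
:class:`FormatError`; statistics that cannot be computed on the given data
(zero variance, no reference latencies, degenerate tests) raise
:class:`DegenerateStatisticsError`.  The CLI maps these onto exit codes 2
and 3 respectively.
"""


class CourtshipSelectError(Exception):
    """Base class for all package errors."""


class FormatError(CourtshipSelectError, ValueError):
    """Input file is structurally unreadable (e.g. a required column is missing)."""


class ValidationError(CourtshipSelectError, ValueError):
    """Input parsed but violates a domain invariant."""


class DegenerateStatisticsError(CourtshipSelectError, ValueError):
    """A statistic is undefined or degenerate on the supplied data."""


class NoReferenceLatencyError(DegenerateStatisticsError):
    """A censoring window was requested for a group with zero successful trials."""
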
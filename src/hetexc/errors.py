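"""Exception hierarchy for hetexc.

All errors raised by the library derive from :class:`HetexcError` so that
callers (and the CLI) can distinguish data problems from programming bugs.
"""


class HetexcError(Exception):
    """Base class for all hetexc errors."""


class InvalidInputError(HetexcError, ValueError):
    """An argument violates a documented precondition."""


class UntestableSiteError(HetexcError):
    """The site is monomorphic (no minor alleles): the exact HWE test is
    undefined, which is deliberately distinct from any P value."""


class UndefinedMetricError(HetexcError):
    """A metric has no defined value for this input (e.g. VCNAB of a
    histogram with zero carriers)."""


class UndefinedRatioError(HetexcError):
    """0/0 fold ratio."""


class FormatError(HetexcError):
    """An input file does not conform to the expected format."""


class MalformedIntervalError(FormatError):
    """A BED interval has start >= end."""
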
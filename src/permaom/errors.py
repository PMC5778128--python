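"""Exception hierarchy.

Every error raised by the package derives from :class:`PermaomError`, so
callers can catch one type at a pipeline boundary while tests can assert
on the specific failure mode.
"""


class PermaomError(Exception):
    """Base class for all permaom errors."""


class ProfileFormatError(PermaomError):
    """A profile file does not follow the canonical CSV dialect."""


class ValidationError(PermaomError):
    """A domain object violates one of its invariants."""


class ParameterError(PermaomError):
    """An operation was called with inconsistent or out-of-range parameters."""


class InsufficientDataError(PermaomError):
    """A profile does not carry enough co-measured records for an operation."""


class UndefinedModelError(PermaomError):
    """The isotope mass-balance model is undefined (alpha_ox == alpha_trans)."""


class UndefinedIndexError(PermaomError):
    """A lipid index or ratio has a zero denominator."""


class GeometryError(PermaomError):
    """A headspace sample has a non-positive headspace volume."""


class UndefinedBasisError(PermaomError):
    """The pore-water basis of a headspace sample is zero (water_content == 0)."""
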
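"""Exception hierarchy.

Every parser and scorer raises a subclass of :class:`RefqualError`; callers
can catch the base class to treat any input problem uniformly, or the
specific subclasses to distinguish malformed files from out-of-domain values.
"""


class RefqualError(Exception):
    """Base class for all refqual errors."""


class ParseError(RefqualError):
    """A file or text block could not be interpreted in its declared dialect."""


class ValidationError(RefqualError):
    """A record was parsed but violates a domain invariant."""


class DomainError(RefqualError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class DegenerateCohortError(RefqualError):
    """A cohort-relative statistic is undefined for this cohort (e.g. zero variance)."""
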
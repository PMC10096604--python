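"""Exception hierarchy shared across the package.

All validation-type failures derive from :class:`ValidationError` so callers
(and the CLI exit-code mapping) can treat them uniformly.
"""


class APDKitError(Exception):
    """Base class for all apdkit errors."""


class ValidationError(APDKitError, ValueError):
    """Input violates a documented contract (bad codes, duplicate IDs, bad thresholds)."""


class NoDataError(ValidationError):
    """An operation ended with zero usable loci or samples."""


class SizeError(ValidationError):
    """A size precondition failed (too few samples, k larger than n, ...)."""
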
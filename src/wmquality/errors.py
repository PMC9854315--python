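"""Exception hierarchy for the wmquality pipeline."""


class WmQualityError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WmQualityError):
    """A dataset file does not have the expected tidy-CSV layout."""


class ValidationError(WmQualityError):
    """A record or pattern violates a structural invariant."""


class ProfilingError(WmQualityError):
    """A data pattern has too few responses to compute RT fences."""


class EligibilityError(WmQualityError):
    """A pattern lacks the trial types a benchmark needs."""


class SummaryError(WmQualityError):
    """Too few patterns to summarise a cohort."""


class DomainError(WmQualityError):
    """A statistical primitive was called outside its domain."""
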
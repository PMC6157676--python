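"""Exception hierarchy for the charcoal-compositing pipeline."""


class CharcompError(Exception):
    """Base class for all package errors."""


class FormatError(CharcompError):
    """A tabular input does not have the required structure (e.g. a missing column)."""


class ValidationError(CharcompError):
    """An input value violates a domain invariant (bounds, duplicates, signs)."""


class DegenerateRecordError(CharcompError):
    """A record cannot be standardized (constant values, zero variance)."""


class EstimationError(CharcompError):
    """Too little data for a statistical estimate (lambda fit, trend, segmentation)."""


class RefusalError(CharcompError):
    """A brute-force oracle was asked for more enumeration than it permits."""
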
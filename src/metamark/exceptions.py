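"""Exception hierarchy for the metamark pipeline."""


class MetamarkError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(MetamarkError, ValueError):
    """A configuration field is invalid or inconsistent."""


class DegenerateScaleError(MetamarkError, ValueError):
    """A normalization divisor is zero (e.g. an all-zero batch-marker block)."""


class DomainError(MetamarkError, ValueError):
    """A value falls outside the mathematical domain of a transform."""


class ClassDegeneracyError(MetamarkError, ValueError):
    """An operation requiring two classes saw fewer than two."""


class InsufficientDataError(MetamarkError, ValueError):
    """Too few samples for the requested operation."""


class ParseError(MetamarkError, ValueError):
    """A data file violates the expected schema."""
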
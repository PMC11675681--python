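"""Exception hierarchy shared across the package."""


class HraSleepError(Exception):
    """Base class for all package errors."""


class FormatError(HraSleepError, ValueError):
    """A file row could not be parsed."""


class EmptyInputError(HraSleepError, ValueError):
    """An input (file, series, table) contained no usable data."""


class LabelError(HraSleepError, ValueError):
    """An unknown sleep-stage label was encountered."""


class StructureError(HraSleepError, ValueError):
    """Hypnogram bouts overlap, leave gaps, or are otherwise malformed."""


class CoverageError(HraSleepError, ValueError):
    """A segment lies (partly) outside the hypnogram span."""


class InsufficientDataError(HraSleepError, ValueError):
    """Too few beats for the requested descriptor."""


class ConfigError(HraSleepError, ValueError):
    """Invalid configuration (unknown transition pair, bad matrix, ...)."""


class SchemaError(HraSleepError, KeyError):
    """A required column is missing or lengths disagree."""


class SplitError(HraSleepError, ValueError):
    """Train/test subject split cannot be constructed."""


class DegenerateResponseError(HraSleepError, ValueError):
    """The binary response has a single class; the model is not estimable."""


class FitError(HraSleepError, RuntimeError):
    """Model fitting failed (separation, non-convergence)."""


class UndefinedMetricError(HraSleepError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""
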
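"""Exception hierarchy shared across the pipeline stages."""


class DermaugError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DermaugError, ValueError):
    """An input violates a documented precondition.

    The message always names the offending field or column.
    """


class CapabilityError(DermaugError, RuntimeError):
    """An optional backend (CTGAN/TVAE/SHAP library, deep-learning framework)
    is not available in the running environment.

    The core pipeline never requires the missing capability; callers may catch
    this and fall back to an always-available path (e.g. SMOTE).
    """


class SegmentationEmptyError(DermaugError, RuntimeError):
    """The fallback segmenter found no foreground component."""


class NoPairsError(DermaugError, RuntimeError):
    """A co-occurrence style operator found no valid in-mask pixel pair."""


class InsufficientSupportError(DermaugError, RuntimeError):
    """A texture family was asked to run on a lesion smaller than its minimum
    support (e.g. fewer than two valid pairs, or less than one wavelet block).

    The message names the family.
    """
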
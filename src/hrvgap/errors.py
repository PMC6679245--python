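"""Exception types shared across the package."""


class HrvGapError(Exception):
    """Base class for all hrvgap errors."""


class InvalidParameterError(HrvGapError, ValueError):
    """A parameter is outside its valid domain."""


class ShapeError(HrvGapError, ValueError):
    """Two sequences that must align have different lengths."""


class DomainError(HrvGapError, ValueError):
    """A kernel was evaluated outside its support."""


class DegenerateSupportError(HrvGapError, ValueError):
    """Interpolation support points coincide."""


class DegenerateWindowError(HrvGapError, ValueError):
    """Too few retained beats to operate on a window."""


class UnsupportedCombinationError(HrvGapError, ValueError):
    """A (how, method) pipeline combination that is rejected by design."""


class FormatError(HrvGapError, ValueError):
    """Malformed input file; message names the offending line."""
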
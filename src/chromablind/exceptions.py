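"""Exception hierarchy used across the pipeline.

Validation failures raise subclasses of :class:`ChromablindError` so callers
(and the CLI, which maps them onto exit codes) can distinguish bad input
shapes from legitimately degenerate data.
"""


class ChromablindError(Exception):
    """Base class for all package-specific errors."""


class ShapeMismatchError(ChromablindError, ValueError):
    """Two images (or arrays) that must share dimensions do not."""


class ChannelError(ChromablindError, ValueError):
    """Input image does not have exactly three colour channels."""


class RangeError(ChromablindError, ValueError):
    """8-bit channel values outside [0, 255], or non-finite numeric input."""


class NoChangeError(ChromablindError, ValueError):
    """An image pair is pixel-identical where a colour change is required."""


class InsufficientDataError(ChromablindError, ValueError):
    """Too few samples for a distribution/statistical operation."""


class SingularFitError(ChromablindError, ValueError):
    """Rank-deficient regression design matrix (collinear feature columns)."""


class DegenerateClassError(ChromablindError, ValueError):
    """Classification requested with fewer than two classes present."""


class GamutError(ChromablindError, ValueError):
    """Requested colour-change magnitude is unreachable inside the sRGB gamut."""


class GenerationError(ChromablindError, RuntimeError):
    """Synthetic scene generation failed within the retry budget."""
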
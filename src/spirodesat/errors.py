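"""Exception hierarchy for the spirodesat pipeline."""


class SpirodesatError(Exception):
    """Base class for all package errors."""


class SegmentationError(SpirodesatError):
    """A position-separation rule could not be satisfied.

    The message names the rule that failed (e.g. ``supine-start``,
    ``trendelenburg-start``).
    """


class DegenerateSignalError(SpirodesatError, ValueError):
    """A signal is degenerate for the requested operation (e.g. constant
    input to min-max scaling)."""


class FeatureUndefinedError(SpirodesatError):
    """A feature could not be computed for a case; the message names the
    offending feature or channel/position combination."""


class EmptySelectionError(SpirodesatError):
    """A feature-selection step returned no features."""


class FormatError(SpirodesatError, ValueError):
    """An input file does not conform to the expected format."""
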
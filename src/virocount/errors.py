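"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class PlacementError(ValidationError):
    """Requested spots cannot be placed in the field at the required separation."""


class CalibrationError(ValidationError):
    """A calibration standard is degenerate (rank-deficient or non-positive)."""
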
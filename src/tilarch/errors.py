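"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Input data violates a structural precondition (shape, range, labels)."""


class InvalidConfigError(ValueError):
    """A simulation or model configuration is internally inconsistent."""


class LayoutError(ValueError):
    """A requested mask layout cannot be packed into the image."""


class DegeneratePatientError(ValueError):
    """A patient has no usable tiles at all."""
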
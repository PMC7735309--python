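"""Exception types shared across the package."""


class InvalidConfigError(ValueError):
    """A configuration object violates its invariants."""


class ShapeError(ValueError):
    """Array shapes are inconsistent with the operation's contract."""


class InputError(ValueError):
    """Input values are invalid (e.g. non-finite pixels)."""


class GenerationError(RuntimeError):
    """Random generation could not satisfy its constraints."""


class TrainingError(RuntimeError):
    """Model training failed (e.g. divergence to non-finite loss)."""
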
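"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(ValueError):
    """An input field/image violates a precondition (shape, emptiness, range)."""


class DegenerateImageError(ValueError):
    """The image histogram is degenerate (e.g. constant) and cannot be split."""


class OptimizerError(RuntimeError):
    """The optimizer produced non-finite values; carries diagnostics in args."""


class GenerationError(RuntimeError):
    """The synthetic-image generator could not satisfy its placement rules."""


class FormatError(ValueError):
    """A file on disk is not in a supported format."""
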
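"""Exception types shared across the pipeline."""


class MassDelimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MassDelimError, ValueError):
    """A parameter is outside its admissible range."""


class ContractError(MassDelimError, ValueError):
    """Inputs violate an operation's contract (shape/size mismatch, empty input)."""


class DegenerateImageError(MassDelimError, ValueError):
    """The image is degenerate for the requested operation (e.g. constant
    intensity, for which min-max membership normalization is undefined)."""


class EmptyMaskError(MassDelimError, ValueError):
    """A metric that needs a non-empty foreground was given an empty mask."""
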
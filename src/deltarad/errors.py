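"""Exception types shared across the package."""


class DeltaRadError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DeltaRadError, ValueError):
    """An argument or configuration value is outside its admissible range."""


class DegenerateInputError(DeltaRadError, ValueError):
    """Input is structurally valid but degenerate (constant volume, empty mask, ...)."""


class SchemaError(DeltaRadError, ValueError):
    """Tabular inputs do not match the expected column/index schema."""
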
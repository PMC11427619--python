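"""Exception hierarchy for tempagree."""


class TempAgreeError(Exception):
    """Base class for all tempagree errors."""


class SchemaError(TempAgreeError, ValueError):
    """Input file does not expose the required columns or device labels."""


class IntegrityError(TempAgreeError, ValueError):
    """Data violate a structural invariant (e.g. duplicated readings)."""


class ConfigurationError(TempAgreeError, ValueError):
    """Invalid analysis or simulation configuration."""


class DegenerateDataError(TempAgreeError, ValueError):
    """Data carry no usable variation for the requested estimate."""


class UndefinedInputError(TempAgreeError, ValueError):
    """Operation is undefined for the given (typically empty) input."""
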
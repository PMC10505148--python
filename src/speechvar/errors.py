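"""Exception hierarchy.

All package-raised errors derive from :class:`SpeechVarError` so callers can
catch one base class; subclasses distinguish parse, schema, validation,
configuration and inference failures.
"""


class SpeechVarError(Exception):
    """Base class for all errors raised by speechvar."""


class ParseError(SpeechVarError):
    """A file could not be parsed (carries the offending line where known)."""


class SchemaError(SpeechVarError):
    """A tabular input is missing required columns or has the wrong layout."""


class ValidationError(SpeechVarError):
    """Data violate a structural invariant (ordering, overlap, sign, ...)."""


class ConfigError(SpeechVarError):
    """A configuration value is missing, inconsistent or infeasible."""


class UnsupportedCombinationError(SpeechVarError):
    """A measure/task combination the protocol does not define."""


class InferenceError(SpeechVarError):
    """A statistical model cannot be fit on the data provided."""
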
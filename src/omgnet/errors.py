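"""Exception hierarchy shared across the package."""


class OmgnetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(OmgnetError):
    """A record, column, or cell does not conform to the declared variables."""


class ConfigurationError(OmgnetError):
    """A structure, count set, or config is internally inconsistent."""


class InferenceError(OmgnetError):
    """A query cannot be answered (e.g. zero-probability evidence)."""


class ValidationInputError(OmgnetError):
    """An evaluation was requested on an empty or ill-posed record set."""
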
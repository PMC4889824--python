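"""Exception hierarchy shared across gesturekit."""


class GestureKitError(Exception):
    """Base class for all gesturekit errors."""


class ValidationError(GestureKitError):
    """An object or argument violates a declared invariant."""


class MalformedInputError(ValidationError):
    """An input file cannot be parsed into the expected shape."""


class ConfigurationError(GestureKitError):
    """A configuration value is inconsistent with the data it is applied to."""


class TrainingError(GestureKitError):
    """The SVM solver failed on one of the binary subproblems."""


class StateError(GestureKitError):
    """An operation was invoked on an object in the wrong state."""
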
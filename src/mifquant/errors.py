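"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`MifquantError` so callers (and the
CLI) can distinguish user-input problems from internal bugs.
"""


class MifquantError(Exception):
    """Base class for all package errors."""


class SchemaError(MifquantError):
    """A table or file is missing a required column/field."""


class ValidationError(MifquantError):
    """A value violates the data model (non-binary marker, bad label...)."""


class GeometryError(MifquantError):
    """Invalid or degenerate geometry (self-intersection, zero area)."""


class ConfigError(MifquantError):
    """Invalid configuration value or combination."""


class InputError(MifquantError):
    """Empty or otherwise unusable input to a computation."""


class StateError(MifquantError):
    """An operation was called before its prerequisite stage ran."""


class SamplingError(MifquantError):
    """A spatial sampling request cannot be satisfied."""


class QuantificationError(MifquantError):
    """A required compartment or measurement is missing."""


class DependencyError(MifquantError):
    """An upstream pipeline artifact is missing."""
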
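"""Exception hierarchy shared across the package."""


class SemgnnError(Exception):
    """Base class for all package errors."""


class ParseError(SemgnnError):
    """A structure or table file could not be parsed."""


class EmbedError(SemgnnError):
    """3-D conformer embedding failed for a molecule."""


class ConfigurationError(SemgnnError):
    """A requested backend or parameter is unavailable or invalid."""


class SchemaError(SemgnnError):
    """A reaction-table schema does not match the file."""


class ValidationError(SemgnnError):
    """Data violates a stated invariant (e.g. yield outside [0, 100])."""


class AssemblyError(SemgnnError):
    """Graph assembly inputs are inconsistent (e.g. stack length mismatch)."""


class SizeError(SemgnnError):
    """A molecule exceeds the declared maximum atom count of a batch."""


class CapabilityError(SemgnnError):
    """The requested introspection is not supported by this model type."""
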
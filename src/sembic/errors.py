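"""Exception hierarchy shared across the package."""


class SembicError(Exception):
    """Base class for all package-specific errors."""


class UnknownIdentifierError(SembicError, KeyError):
    """A gene or situation id is not present in the host matrix."""


class DimensionError(SembicError, ValueError):
    """An operation received an empty or incompatibly shaped matrix."""


class ParameterError(SembicError, ValueError):
    """A numeric or structural parameter is outside its documented range."""


class FormatError(SembicError, ValueError):
    """A file does not conform to its declared format."""


class ContainmentError(SembicError, ValueError):
    """A query set is not contained in its background set."""


class MappingError(SembicError, ValueError):
    """A term cannot be attributed to exactly one vocabulary side."""


class ValidationError(SembicError, ValueError):
    """A structural invariant (e.g. ontology acyclicity) is violated."""
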
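"""Exception hierarchy shared across the pipeline."""


class NerdcallError(Exception):
    """Base class for all package-specific errors."""


class DataError(NerdcallError):
    """Input data violates a contract (bad table, reference mismatch, ...)."""


class ConfigurationError(NerdcallError):
    """A required column, sample, gene or signature is missing or mismatched."""


class FormatError(NerdcallError):
    """A structured input file does not conform to its declared format."""


class VcfParseError(FormatError):
    """A VCF could not be parsed; the message names the offending record."""


class UnclassifiableIndelError(NerdcallError):
    """Raised for complex substitutions that fit no ID-83 channel.

    Catalog construction catches this and counts the variant instead of
    force-classifying it.
    """


class GenerationError(NerdcallError):
    """The simulator could not realize a requested variant on the reference."""
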
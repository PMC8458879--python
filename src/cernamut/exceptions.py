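"""Exception hierarchy shared across the pipeline stages."""


class CernamutError(Exception):
    """Base class for all package errors."""


class ConfigError(CernamutError, ValueError):
    """Invalid configuration (negative counts, rates outside [0, 1], ...)."""


class FormatError(CernamutError, ValueError):
    """A structured input file violates its format contract."""


class ValidationError(CernamutError, ValueError):
    """A record violates a domain invariant (e.g. ref == alt)."""


class AlphabetError(CernamutError, ValueError):
    """A sequence contains characters outside the RNA alphabet."""


class ReferenceMismatchError(CernamutError, ValueError):
    """Stated reference allele disagrees with the transcript sequence."""


class MissingSequenceError(CernamutError, KeyError):
    """A referenced transcript or miRNA has no sequence entry."""


class InestimableError(CernamutError, ValueError):
    """A statistic cannot be estimated from the given data (zero variance,
    no events, empty group...)."""
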
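"""Exception types raised across the package."""


class AmplichimError(Exception):
    """Base class for package errors."""


class AmbiguousDesignError(AmplichimError):
    """A guide (or TALEN arm) has zero or multiple placements on the reference."""


class DegenerateDesignError(AmplichimError):
    """An edit design collapses to a no-op (e.g. identical cut sites)."""


class ConfigurationError(AmplichimError):
    """Invalid or inconsistent user configuration."""


class AnnotationError(AmplichimError):
    """Coding-frame annotation cannot be reconciled with the edited allele."""


class InsufficientDataError(AmplichimError):
    """Not enough called reads to support an estimate."""


class UndiagnosableDesignError(AmplichimError):
    """WT and edited alleles produce identical diagnostic fragment patterns."""
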
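"""Exception hierarchy."""


class OncoceaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OncoceaError, ValueError):
    """Invalid, incomplete, or inconsistent model configuration."""


class EvidenceError(OncoceaError, ValueError):
    """Invalid trial-evidence input (bad CI, zero cells, disconnected network)."""


class StructuralError(OncoceaError, ValueError):
    """Model inputs structurally inconsistent (e.g. PFS curve above OS curve)."""


class FitError(OncoceaError, ValueError):
    """Survival-curve fitting cannot proceed on the given points."""
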
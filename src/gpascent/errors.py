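"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A setting is outside its valid range or inconsistent with another setting."""


class ConstraintViolation(ConfigurationError):
    """A hard design constraint was violated (e.g. more QTL than markers)."""


class ArchitectureError(ConfigurationError):
    """The requested trait architecture cannot be built from the genome at hand."""


class ConvergenceSignal(RuntimeError):
    """Raised when an ascent has no direction of improvement (all slopes zero)."""
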
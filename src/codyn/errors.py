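"""Exception hierarchy shared across the pipeline stages."""


class CodynError(Exception):
    """Base class for all package-specific errors."""


class TrajectoryParseError(CodynError):
    """A trajectory file could not be parsed (malformed records, empty file)."""


class StructuralError(CodynError):
    """Models within one trajectory file disagree structurally (atom counts)."""


class SelectionError(CodynError):
    """An atom selection resolved to zero or more than one atom."""


class MappingError(CodynError):
    """Residue correspondence between systems could not be established."""


class AlignmentStateError(CodynError):
    """An operation requiring an aligned trajectory received an unaligned one."""


class DegenerateSpanError(CodynError):
    """A pseudo-trajectory span collapsed to a single point (zero-variance PC)."""


class FitError(CodynError):
    """Nonlinear fit failed to converge; carries best candidate diagnostics."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ConfigError(CodynError):
    """Run configuration is invalid or missing required entries."""
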
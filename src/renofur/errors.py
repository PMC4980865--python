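"""Exception hierarchy shared across the package."""


class RenofurError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RenofurError):
    """Invalid kinetic or acquisition parameters."""


class LayoutError(RenofurError):
    """Phantom geometry cannot be realized on the requested grid."""


class ExtractionError(RenofurError):
    """ROI time-activity extraction failed (e.g. empty ROI)."""


class FitError(RenofurError):
    """A curve fit has too few usable points or is otherwise degenerate."""


class StatsError(RenofurError):
    """Invalid input to a statistical test (sample size, zero variance...)."""


class ConfigError(RenofurError):
    """Invalid run configuration."""
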
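"""Exception hierarchy used across the package."""


class LCMILError(Exception):
    """Base class for package errors."""


class ConfigError(LCMILError):
    """A configuration value is invalid or inconsistent."""


class DegenerateInputError(LCMILError):
    """Input on which the requested operation is mathematically undefined
    (e.g. Otsu on a constant channel, area fraction of empty tissue)."""


class AlignmentError(LCMILError):
    """Two rasters that must share a frame have different shapes."""


class StateError(LCMILError):
    """An object is not in the state the operation requires
    (e.g. assembling a score map from unscored patches)."""


class InfeasibleError(LCMILError):
    """The requested computation cannot be carried out on this input
    (e.g. building bags from an empty patch pool)."""
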
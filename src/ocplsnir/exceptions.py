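"""Exception hierarchy.

Everything derives from :class:`OcplsError` so callers can catch the whole
family; most classes also derive from :class:`ValueError` because they signal
invalid inputs.
"""


class OcplsError(Exception):
    """Base class for all errors raised by this package."""


class GridError(OcplsError, ValueError):
    """Wavenumber grid is invalid or two grids do not match."""


class SpectraFormatError(OcplsError, ValueError):
    """A spectra file could not be parsed (ragged rows, missing records...)."""


class MetadataError(OcplsError, ValueError):
    """Per-sample metadata violates the class/adulterant/level invariant."""


class ReferenceError_(OcplsError, ValueError):
    """Reference spectrum unusable, e.g. zero norm."""


class DegenerateSpectrumError(OcplsError, ValueError):
    """Spectrum has zero variance and cannot be SNV-transformed."""


class SplitError(OcplsError, ValueError):
    """Invalid arguments to the DUPLEX splitter."""


class RankError(OcplsError, ValueError):
    """PLS component extraction failed: requested components exceed rank."""


class ConfigError(OcplsError, ValueError):
    """Invalid generator / MCCV / run configuration."""


class ContaminationError(OcplsError, ValueError):
    """Non-pure samples found in a one-class training set."""


class DegenerateModelError(OcplsError, ValueError):
    """Fitted model has zero error dispersion; no acceptance interval exists."""


class DimensionError(OcplsError, ValueError):
    """Prediction data does not match the model's grid/dimension."""


class MetricUndefinedError(OcplsError, ValueError):
    """Sensitivity or specificity requested with an empty class margin."""
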
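"""Exception hierarchy for the septime pipeline.

Every stage raises a subclass of :class:`SeptimeError` so the CLI can map
failures to exit codes with the stage name attached.
"""


class SeptimeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SeptimeError):
    """An input table is missing mandatory columns or is malformed."""


class EmptyInputError(SeptimeError):
    """No valid rows survived validation."""


class InsufficientDataError(SeptimeError):
    """Too few observations for the requested statistic."""


class GeometryError(SeptimeError):
    """Cell dimensions violate the rod-shape model (e.g. length < diameter)."""


class ShortCellError(SeptimeError):
    """Cell too short to carve a purely cylindrical midcell window."""


class AlignmentError(SeptimeError):
    """Profile registration failed (e.g. zero-variance signal)."""


class DegenerateCurveError(SeptimeError):
    """A binned curve is constant and cannot be min-max normalized."""


class NoOnsetError(SeptimeError):
    """The midcell fluorescence surplus never becomes positive; the protein
    shows no midcell localization in this data set."""


class ConfigError(SeptimeError):
    """Invalid run configuration."""
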
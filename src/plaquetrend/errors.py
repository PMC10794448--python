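"""Exception hierarchy for the plaquetrend pipeline."""


class PlaquetrendError(Exception):
    """Base class for all package errors."""


class InvalidContourError(PlaquetrendError):
    """Contour violates its invariants (too few vertices, self-intersection, zero area)."""


class GeometryInconsistencyError(PlaquetrendError):
    """Lumen/vessel pair violates containment or a ray fails to cross a boundary cleanly."""


class AnchorError(PlaquetrendError):
    """Anchor point for diameter measurement lies outside the contour."""


class SignalError(PlaquetrendError):
    """Longitudinal-signal construction or alignment failure."""


class TooFewSamplesError(SignalError):
    """Fewer samples than the operation requires."""


class NoOverlapError(SignalError):
    """No admissible shift leaves the minimum BL/FU overlap."""


class AlignmentError(SignalError):
    """Paired signals do not share a common aligned grid."""


class InvalidSignalError(SignalError):
    """Signal values outside their physical range (e.g. plaque burden not in [0,100])."""


class ConfigError(PlaquetrendError):
    """Invalid configuration value."""


class DataError(PlaquetrendError):
    """Empty or inconsistent tabular data."""


class MissingDataError(DataError):
    """A required clinical covariate is absent (no imputation is performed)."""
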
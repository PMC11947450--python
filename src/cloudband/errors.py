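"""Exception hierarchy shared across the package."""


class CloudbandError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(CloudbandError):
    """Display or camera geometry with non-positive dimensions."""


class InvalidSpecError(CloudbandError):
    """Stimulus specification that cannot be rendered."""


class AliasingError(InvalidSpecError):
    """Requested frequency content exceeds the display Nyquist limit."""


class ResolutionError(CloudbandError):
    """Pixel pitch too coarse to represent a requested filter frequency."""


class InvalidApertureError(CloudbandError):
    """Aperture placed (partly) off screen."""


class InfeasibleSequenceError(CloudbandError):
    """No presentation order satisfies the no-immediate-repeat constraint."""


class DegenerateDataError(CloudbandError):
    """Input data carries no usable signal (e.g. constant image, flat curve)."""


class EmptySurroundError(CloudbandError):
    """Surround annulus contains no grid sites."""


class FitFailureError(CloudbandError):
    """All optimizer restarts were infeasible or diverged."""


class InsufficientDataError(CloudbandError):
    """Too few trials/reversals/groups for the requested statistic."""


class SchemaError(CloudbandError):
    """A table is missing required columns or has malformed values."""


class IntegrityError(CloudbandError):
    """Stored hash does not match the data on disk, or duplicate keys."""


class ExtrapolationError(CloudbandError):
    """Requested criterion lies outside the observed data range."""
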
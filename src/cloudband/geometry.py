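"""Display and camera geometry: converting pixels and cycles to visual degrees.

The angular size of a flat monitor seen from a viewing distance ``D`` is

    angular_size = 2 * arctan(width / (2 * D))

and the field of view of a camera with a given sensor dimension, crop factor
and focal length is

    FOV = 2 * arctan(sensor / (2 * crop * focal_length)).

Degrees-per-pixel is the angular size divided by the horizontal resolution;
all spatial-frequency conversions (cycles/image -> cycles/degree) go through
these two relations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidGeometryError

__all__ = [
    "DisplayGeometry",
    "CameraGeometry",
    "angular_size_deg",
    "camera_fov_deg",
    "degrees_per_pixel",
]


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical monitor geometry.

    Parameters
    ----------
    monitor_width_cm : float
        Physical width of the display surface, cm.
    viewing_distance_cm : float
        Distance from the eye to the screen, cm.
    resolution_px : tuple of int
        ``(width, height)`` in pixels.
    """

    monitor_width_cm: float
    viewing_distance_cm: float
    resolution_px: tuple[int, int]

    def __post_init__(self) -> None:
        if self.monitor_width_cm <= 0 or self.viewing_distance_cm <= 0:
            raise InvalidGeometryError("monitor width and viewing distance must be > 0")
        w, h = self.resolution_px
        if int(w) <= 0 or int(h) <= 0:
            raise InvalidGeometryError("resolution must be positive")

    @property
    def angular_size_deg(self) -> float:
        return angular_size_deg(self.monitor_width_cm, self.viewing_distance_cm)

    @property
    def deg_per_px(self) -> float:
        return degrees_per_pixel(self)

    @property
    def nyquist_cpd(self) -> float:
        """Highest representable spatial frequency, cycles/degree."""
        return 0.5 / self.deg_per_px


@dataclass(frozen=True)
class CameraGeometry:
    """Camera optics used to assign a field of view to photographs."""

    sensor_dimension_mm: float
    crop_factor: float
    focal_length_mm: float

    def __post_init__(self) -> None:
        if min(self.sensor_dimension_mm, self.crop_factor, self.focal_length_mm) <= 0:
            raise InvalidGeometryError("camera geometry fields must be > 0")

    @property
    def fov_deg(self) -> float:
        return camera_fov_deg(
            self.sensor_dimension_mm, self.crop_factor, self.focal_length_mm
        )


def angular_size_deg(width: float, distance: float) -> float:
    """Total visual angle (degrees) subtended by a flat extent ``width``."""
    if width <= 0 or distance <= 0:
        raise InvalidGeometryError("width and distance must be > 0")
    return math.degrees(2.0 * math.atan(width / (2.0 * distance)))


def camera_fov_deg(sensor: float, crop_factor: float, focal_length: float) -> float:
    """Camera field of view (degrees) from sensor size and effective focal length."""
    if min(sensor, crop_factor, focal_length) <= 0:
        raise InvalidGeometryError("camera geometry fields must be > 0")
    return math.degrees(2.0 * math.atan(sensor / (2.0 * crop_factor * focal_length)))


def degrees_per_pixel(geometry: DisplayGeometry) -> float:
    """Visual degrees per pixel along the horizontal axis of the display."""
    return geometry.angular_size_deg / geometry.resolution_px[0]
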
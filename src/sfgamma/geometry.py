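"""Viewing geometry: converting monitor/observer parameters to pixels per degree.

Spatial-frequency content of a stimulus is only meaningful in units of
cycles per degree of visual angle (cpd), which depends on the physical
pixel pitch of the display and the viewing distance.  All conversions use
the exact arctangent relation rather than the small-angle approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ViewingGeometry", "pixels_per_degree", "degrees_subtended"]

_CM_PER_INCH = 2.54


@dataclass(frozen=True)
class ViewingGeometry:
    """Physical display + observer geometry.

    Parameters
    ----------
    diagonal_inches : monitor diagonal in inches.
    aspect : (width, height) aspect ratio, e.g. ``(4, 3)``.
    resolution : (width, height) in pixels.
    distance_cm : eye-to-screen distance in centimetres.
    """

    diagonal_inches: float
    aspect: tuple[float, float]
    resolution: tuple[int, int]
    distance_cm: float

    def __post_init__(self) -> None:
        if self.diagonal_inches <= 0:
            raise ValueError("monitor diagonal must be positive")
        if any(a <= 0 for a in self.aspect):
            raise ValueError("aspect ratio components must be positive")
        if any(r <= 0 for r in self.resolution):
            raise ValueError("resolution must be positive")
        if self.distance_cm <= 0:
            raise ValueError("viewing distance must be positive")

    @property
    def pixel_pitch_cm(self) -> float:
        """Physical width of one pixel in cm (assumes square pixels)."""
        aw, ah = self.aspect
        hyp = math.hypot(aw, ah)
        width_cm = self.diagonal_inches * _CM_PER_INCH * aw / hyp
        return width_cm / self.resolution[0]

    @property
    def pixels_per_degree(self) -> float:
        return pixels_per_degree(self)


def pixels_per_degree(geom: ViewingGeometry) -> float:
    """Pixels subtending one degree of visual angle at the screen centre.

    One pixel of pitch *p* viewed from distance *d* subtends
    ``2 * atan(p / (2 d))``; the reciprocal (in degrees) is the pixel
    density per degree.
    """
    theta_deg = math.degrees(2.0 * math.atan(geom.pixel_pitch_cm / (2.0 * geom.distance_cm)))
    return 1.0 / theta_deg


def degrees_subtended(n_pixels: float, geom: ViewingGeometry) -> float:
    """Exact visual angle (degrees) subtended by ``n_pixels`` centred on fixation."""
    if n_pixels < 0:
        raise ValueError("pixel extent must be non-negative")
    half = n_pixels * geom.pixel_pitch_cm / 2.0
    return math.degrees(2.0 * math.atan(half / geom.distance_cm))
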
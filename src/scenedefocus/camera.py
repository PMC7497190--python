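"""Pinhole camera model mapping pixels to visual angles.

The depth camera is modelled as an ideal pinhole: a pixel column ``u`` maps to
a horizontal visual angle ``theta_x = atan((u - u0) / f_x)`` and a row ``v`` to
a vertical angle ``theta_y = atan((v0 - v) / f_y)`` (positive up; row 0 is the
top of the image).  Focal lengths in pixels are derived from the configured
field of view, ``f_x = (W/2) / tan(hfov/2)`` and likewise vertically.

Eccentricity is the radial coordinate of the planar-angle chart,
``eps = sqrt(theta_x**2 + theta_y**2)``, so that the circular analysis field of
radius 30 deg has area exactly ``pi * 30**2`` square degrees in the coordinates
over which dioptric volumes are integrated.  For a time-of-flight device with a
~70 x 60 deg field this differs from the true ray-to-axis angle by less than
1.5 deg at the edge of the 30 deg field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidConfigurationError

#: Nominal resolution and field of view of a Kinect-v2-like depth camera.
DEFAULT_WIDTH = 512
DEFAULT_HEIGHT = 434
DEFAULT_HFOV = 70.6
DEFAULT_VFOV = 60.0


@dataclass(frozen=True)
class CameraModel:
    """Pinhole depth-camera geometry.

    Parameters
    ----------
    width, height : int
        Image resolution in pixels (>= 2 each).
    horizontal_fov, vertical_fov : float
        Full field of view in degrees, in (0, 180).
    principal_point : tuple of float, optional
        (u0, v0) pixel coordinates of the optical axis; defaults to the
        image centre ``((width-1)/2, (height-1)/2)``.
    """

    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    horizontal_fov: float = DEFAULT_HFOV
    vertical_fov: float = DEFAULT_VFOV
    principal_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise InvalidConfigurationError(
                f"camera resolution must be >= 2 in both axes, got "
                f"{self.width}x{self.height}"
            )
        for name, fov in (("horizontal", self.horizontal_fov),
                          ("vertical", self.vertical_fov)):
            if not 0.0 < fov < 180.0:
                raise InvalidConfigurationError(
                    f"{name} field of view must lie in (0, 180) deg, got {fov}"
                )

    # -- derived geometry ---------------------------------------------------

    @property
    def u0(self) -> float:
        if self.principal_point is not None:
            return float(self.principal_point[0])
        return (self.width - 1) / 2.0

    @property
    def v0(self) -> float:
        if self.principal_point is not None:
            return float(self.principal_point[1])
        return (self.height - 1) / 2.0

    @property
    def fx(self) -> float:
        """Horizontal focal length in pixels."""
        return (self.width / 2.0) / math.tan(math.radians(self.horizontal_fov) / 2.0)

    @property
    def fy(self) -> float:
        """Vertical focal length in pixels."""
        return (self.height / 2.0) / math.tan(math.radians(self.vertical_fov) / 2.0)

    @property
    def centre_index(self) -> tuple[int, int]:
        """(row, col) of the pixel nearest the principal point."""
        return int(round(self.v0)), int(round(self.u0))

    def pixel_angles(self) -> tuple[np.ndarray, np.ndarray]:
        """Planar visual angles of every pixel centre.

        Returns
        -------
        theta_x : ndarray of shape (width,)
            Horizontal angle in degrees, positive rightwards.
        theta_y : ndarray of shape (height,)
            Vertical angle in degrees, positive upwards (decreasing with row).
        """
        u = np.arange(self.width, dtype=float)
        v = np.arange(self.height, dtype=float)
        theta_x = np.degrees(np.arctan((u - self.u0) / self.fx))
        theta_y = np.degrees(np.arctan((self.v0 - v) / self.fy))
        return theta_x, theta_y

    def eccentricity(self) -> np.ndarray:
        """Per-pixel eccentricity grid (degrees), shape (height, width)."""
        tx, ty = self.pixel_angles()
        return np.hypot(tx[np.newaxis, :], ty[:, np.newaxis])
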
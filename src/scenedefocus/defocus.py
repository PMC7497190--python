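"""Conversion of calibrated depth maps into scene defocus maps.

A scene point at eye-referenced distance ``d`` metres presents a vergence of
``1/d`` dioptres.  Defocus is expressed relative to the central visual target:

    F(p) = 1/d(p) - V_t,        V_t = 1 / d(centre)

so the target itself is 0 D, points nearer than the target are positive
(hyperopic defocus) and points farther are negative (myopic defocus).  Pixels
with no usable depth — windows, surfaces beyond the device range — are treated
as optically at infinity (vergence 0), i.e. ``F = -V_t``, so every pixel of
the map carries a finite value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel
from .depth import DepthMap
from .exceptions import CalibrationError, InvalidInputError


@dataclass
class DefocusMap:
    """Signed defocus values on a separable planar-angle grid.

    Attributes
    ----------
    values : ndarray, shape (H, W)
        Defocus in dioptres (+ hyperopic, - myopic).
    theta_x : ndarray, shape (W,)
        Horizontal planar angle of each column, degrees, positive right.
    theta_y : ndarray, shape (H,)
        Vertical planar angle of each row, degrees, positive up.
    target_vergence : float
        Vergence of the central visual target (D).
    provenance : dict
        Free-form processing metadata (frames averaged, calibration offset...).
    """

    values: np.ndarray
    theta_x: np.ndarray
    theta_y: np.ndarray
    target_vergence: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.theta_x = np.asarray(self.theta_x, dtype=float)
        self.theta_y = np.asarray(self.theta_y, dtype=float)
        if self.values.shape != (self.theta_y.size, self.theta_x.size):
            raise InvalidInputError(
                "values must have shape (len(theta_y), len(theta_x))"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("defocus values must all be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def eccentricity(self) -> np.ndarray:
        """Planar-angle radius sqrt(theta_x^2 + theta_y^2), degrees, (H, W)."""
        return np.hypot(self.theta_x[np.newaxis, :], self.theta_y[:, np.newaxis])

    @property
    def polar_angle(self) -> np.ndarray:
        """Polar angle atan2(theta_y, theta_x) in degrees, (H, W).

        0 deg points right, 90 deg up, consistent with the quadrant wedges.
        """
        return np.degrees(
            np.arctan2(self.theta_y[:, np.newaxis], self.theta_x[np.newaxis, :])
        )

    def plot(self, ax=None, max_eccentricity: float | None = 30.0, **imshow_kw):
        """Render the defocus map with matplotlib (degrees on both axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        extent = [self.theta_x[0], self.theta_x[-1],
                  self.theta_y[-1], self.theta_y[0]]
        imshow_kw.setdefault("cmap", "RdBu_r")
        vmax = np.abs(self.values).max() or 1.0
        imshow_kw.setdefault("vmin", -vmax)
        imshow_kw.setdefault("vmax", vmax)
        im = ax.imshow(self.values, extent=extent, **imshow_kw)
        if max_eccentricity is not None:
            circle = plt.Circle((0, 0), max_eccentricity, fill=False,
                                color="k", lw=0.8)
            ax.add_patch(circle)
        ax.set_xlabel("horizontal angle (deg)")
        ax.set_ylabel("vertical angle (deg)")
        ax.figure.colorbar(im, ax=ax, label="defocus (D)")
        return ax


def to_defocus(dmap: DepthMap, camera: CameraModel,
               target_vergence: float | None = None) -> DefocusMap:
    """Invert a calibrated depth map to dioptres relative to the target.

    Parameters
    ----------
    dmap : DepthMap
        Must already be calibrated (``calibration_offset`` set).
    camera : CameraModel
        Supplies the pixel-to-angle mapping.
    target_vergence : float, optional
        Override for V_t; by default taken as 1 / centre-pixel depth, which
        requires a valid centre pixel.
    """
    if dmap.calibration_offset is None:
        raise CalibrationError("depth map must be calibrated before defocus "
                               "conversion")
    if dmap.shape != (camera.height, camera.width):
        raise InvalidInputError(
            f"depth map shape {dmap.shape} does not match camera resolution "
            f"{(camera.height, camera.width)}"
        )
    if target_vergence is None:
        if not dmap.centre_valid:
            raise CalibrationError(
                "centre pixel invalid and no explicit target vergence given"
            )
        target_vergence = 1.0 / dmap.centre_depth
    vergence = np.where(dmap.valid, 1.0 / np.where(dmap.valid, dmap.depth, 1.0), 0.0)
    values = vergence - target_vergence
    theta_x, theta_y = camera.pixel_angles()
    return DefocusMap(
        values=values,
        theta_x=theta_x,
        theta_y=theta_y,
        target_vergence=float(target_vergence),
        provenance={
            "n_frames": dmap.n_frames,
            "calibration_offset_m": dmap.calibration_offset,
            "n_invalid_pixels": int((~dmap.valid).sum()),
        },
    )
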
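"""Depth-frame containers, frame averaging and viewpoint calibration.

Depth values are perpendicular (z-axis) distances in metres, the convention of
time-of-flight depth streams.  A reading of 0 in an image file is the invalid
sentinel (no return, out of range, or a masked window region).

The camera sits a fixed distance behind the subject's eye, so raw depths are
camera-referenced.  ``calibrate`` shifts the whole map by a constant additive
offset so that the centre pixel equals the tape-measured eye-to-target
distance, making every depth eye-referenced.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import CalibrationError, InvalidInputError

#: Working range of the depth device in metres.
DEFAULT_MAX_RANGE = 4.5


@dataclass
class DepthFrame:
    """One raw depth image: per-pixel depth (m) plus validity flags."""

    depth: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.depth.ndim != 2 or self.depth.shape != self.valid.shape:
            raise InvalidInputError(
                "depth and valid must be 2-D arrays of identical shape"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass
class DepthMap:
    """Frame-averaged depth map with provenance.

    ``calibration_offset`` is ``None`` until :func:`calibrate` has been
    applied; afterwards it records the constant (metres) subtracted from every
    valid pixel.
    """

    depth: np.ndarray
    valid: np.ndarray
    n_frames: int = 1
    frames_per_pixel: np.ndarray | None = None
    calibration_offset: float | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.depth.shape != self.valid.shape:
            raise InvalidInputError("depth and valid shapes differ")
        if self.frames_per_pixel is None:
            self.frames_per_pixel = self.valid.astype(int) * self.n_frames

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    @property
    def centre_index(self) -> tuple[int, int]:
        h, w = self.depth.shape
        return (h - 1) // 2, (w - 1) // 2

    @property
    def centre_depth(self) -> float:
        return float(self.depth[self.centre_index])

    @property
    def centre_valid(self) -> bool:
        return bool(self.valid[self.centre_index])


def average_frames(frames: list[DepthFrame]) -> DepthMap:
    """Superimpose repeated captures of a static scene into one depth map.

    Each pixel is averaged over the frames in which it holds a valid reading;
    pixels valid in no frame are flagged invalid.
    """
    if not frames:
        raise InvalidInputError("average_frames requires at least one frame")
    shape = frames[0].shape
    for f in frames[1:]:
        if f.shape != shape:
            raise InvalidInputError(
                f"frame resolutions differ: {shape} vs {f.shape}"
            )
    stack = np.stack([np.where(f.valid, f.depth, 0.0) for f in frames])
    counts = np.stack([f.valid for f in frames]).sum(axis=0)
    valid = counts > 0
    total = stack.sum(axis=0)
    depth = np.where(valid, total / np.maximum(counts, 1), 0.0)
    return DepthMap(depth=depth, valid=valid, n_frames=len(frames),
                    frames_per_pixel=counts)


def apply_offset(dmap: DepthMap, offset: float) -> DepthMap:
    """Subtract a constant depth offset; pixels driven <= 0 become invalid."""
    depth = np.where(dmap.valid, dmap.depth - offset, 0.0)
    valid = dmap.valid & (depth > 0)
    depth = np.where(valid, depth, 0.0)
    return replace(dmap, depth=depth, valid=valid,
                   calibration_offset=float(offset))


def calibrate(dmap: DepthMap, measured_distance: float) -> DepthMap:
    """Reference the map to the eye using the tape-measured viewing distance.

    The constant offset ``centre depth - measured_distance`` is subtracted from
    every valid pixel, after which the centre pixel equals the measured
    eye-to-target distance exactly.
    """
    if measured_distance <= 0:
        raise CalibrationError("measured viewing distance must be positive")
    if not dmap.centre_valid:
        raise CalibrationError(
            "centre pixel holds no valid depth; cannot calibrate to the "
            "central visual target"
        )
    offset = dmap.centre_depth - measured_distance
    return apply_offset(dmap, offset)


# -- file I/O ---------------------------------------------------------------

_MM_PER_M = 1000.0


def read_depth_frame(path: str | os.PathLike,
                     max_range: float = DEFAULT_MAX_RANGE) -> DepthFrame:
    """Read a depth frame from disk.

    ``.png`` files are 16-bit grayscale with millimetre values and 0 as the
    invalid sentinel; any other extension is parsed as a whitespace-delimited
    text matrix of metres (0 or NaN invalid).  Readings beyond ``max_range``
    are flagged invalid.
    """
    path = os.fspath(path)
    if path.lower().endswith(".png"):
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path))
        if raw.ndim != 2:
            raise InvalidInputError(f"{path}: expected single-channel depth PNG")
        depth = raw.astype(float) / _MM_PER_M
        valid = raw > 0
    else:
        depth = np.atleast_2d(np.loadtxt(path, dtype=float))
        valid = np.isfinite(depth) & (depth > 0)
        depth = np.where(valid, depth, 0.0)
    valid &= depth <= max_range
    depth = np.where(valid, depth, 0.0)
    return DepthFrame(depth=depth, valid=valid)


def write_depth_frame(frame: DepthFrame, path: str | os.PathLike) -> None:
    """Write a depth frame (PNG in mm with 0-sentinel, or text in metres)."""
    path = os.fspath(path)
    if path.lower().endswith(".png"):
        import imageio.v3 as iio

        mm = np.where(frame.valid, np.round(frame.depth * _MM_PER_M), 0.0)
        iio.imwrite(path, np.clip(mm, 0, np.iinfo(np.uint16).max).astype(np.uint16))
    else:
        np.savetxt(path, np.where(frame.valid, frame.depth, 0.0), fmt="%.6f")
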
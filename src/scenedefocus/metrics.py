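"""Scalar summaries of a defocus map: dioptric volumes and dispersion.

The dioptric volume (DV) of a region is the trapezoidal double integral of the
defocus map over the planar visual angles (theta_x, theta_y), in units of
dioptre x degree^2 (D-deg-deg).  It measures the net amount of defocus a scene
presents relative to the central target over the central 30 deg field.  Two
potency conventions are supported: *linear*, in which hyperopic (+) and myopic
(-) defocus cancel one-for-one, and *double_myopic* (DV_2M), in which myopic
defocus is given twice the weight — the spatial-integration asymmetry reported
in chick experiments.

The analysis field {eccentricity <= 30 deg} is decomposed into six 5-degree
annular rings and four 90-degree quadrant wedges (right, up, left, down,
bounded by the +-45 deg diagonals).  Because the integrand is zero-filled
outside each region and trapezoidal integration is linear, the ring DVs and
the quadrant DVs each sum exactly to the full-field DV.

SD_D, the dispersion of the scene's dioptric profile, is the unweighted sample
standard deviation (n-1 denominator) of the defocus values inside the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .defocus import DefocusMap
from .exceptions import InvalidInputError

MAX_ECCENTRICITY = 30.0
RING_WIDTH = 5.0

QUADRANT_LABELS = ("R", "U", "L", "D")


@dataclass(frozen=True)
class RegionMask:
    """Pixel membership of one analysis region of a defocus map."""

    label: str
    member: np.ndarray
    ecc_bounds: tuple[float, float]
    sector_bounds: tuple[float, float] | None = None  # polar deg, quadrants only

    @property
    def n_pixels(self) -> int:
        return int(self.member.sum())


def _integrate(values: np.ndarray, theta_x: np.ndarray,
               theta_y: np.ndarray) -> float:
    """Orientation-free 2-D trapezoidal integral over a separable grid."""
    inner = np.trapezoid(values, theta_x, axis=1)
    total = np.trapezoid(inner, theta_y)
    sign = 1.0
    if theta_x[-1] < theta_x[0]:
        sign = -sign
    if theta_y[-1] < theta_y[0]:
        sign = -sign
    return float(sign * total)


def make_masks(dmap: DefocusMap,
               max_eccentricity: float = MAX_ECCENTRICITY,
               ring_width: float = RING_WIDTH) -> list[RegionMask]:
    """Build the FULL disc, annular-ring and quadrant-wedge masks.

    Ring ``RING_k`` (k = ring_width, 2*ring_width, ...) holds pixels with
    eccentricity in [k - ring_width, k), the outermost ring closed at
    ``max_eccentricity``.  Quadrants are the four 90-deg wedges centred on the
    right/up/left/down directions.  Every FULL pixel belongs to exactly one
    ring and exactly one quadrant.
    """
    n_rings = max_eccentricity / ring_width
    if abs(n_rings - round(n_rings)) > 1e-9:
        raise InvalidInputError("ring width must divide the maximum eccentricity")
    n_rings = int(round(n_rings))

    ecc = dmap.eccentricity
    full = ecc <= max_eccentricity
    masks = [RegionMask("FULL", full, (0.0, max_eccentricity))]

    for i in range(n_rings):
        lo, hi = i * ring_width, (i + 1) * ring_width
        if i == n_rings - 1:
            member = full & (ecc >= lo)
        else:
            member = (ecc >= lo) & (ecc < hi)
        masks.append(RegionMask(f"RING_{int(hi)}", member, (lo, hi)))

    pol = dmap.polar_angle
    sectors = {"R": (-45.0, 45.0), "U": (45.0, 135.0),
               "L": (135.0, 225.0), "D": (225.0, 315.0)}
    # one shared quadrant index per pixel (0=R, 1=U, 2=L, 3=D) so the four
    # wedges partition the disc exactly even at the float diagonal boundaries
    qi = (np.floor(np.mod(pol + 45.0, 360.0) / 90.0).astype(int)) % 4
    for i, (lab, (lo, hi)) in enumerate(sectors.items()):
        member = full & (qi == i)
        masks.append(RegionMask(f"QUAD_{lab}", member, (0.0, max_eccentricity),
                                sector_bounds=(lo, hi)))

    if ecc.max() < max_eccentricity:
        warnings.warn(
            f"angular grid extends only to {ecc.max():.1f} deg; the "
            f"{max_eccentricity:.0f} deg analysis field is not fully covered",
            stacklevel=2,
        )
    return masks


def mask_coverage(dmap: DefocusMap, full_mask: RegionMask,
                  max_eccentricity: float = MAX_ECCENTRICITY) -> float:
    """Fraction of the ideal disc area covered by the gridded FULL mask."""
    area = _integrate(full_mask.member.astype(float), dmap.theta_x, dmap.theta_y)
    return area / (np.pi * max_eccentricity**2)


def dioptric_volume(dmap: DefocusMap, mask: RegionMask,
                    potency: str = "linear") -> float:
    """Trapezoidal double integral of (weighted) defocus over a region, D-deg^2.

    ``potency='linear'`` integrates F as-is; ``'double_myopic'`` doubles
    negative (myopic) values before integration.  Pixels outside the mask
    contribute zero, which makes ring/quadrant volumes exactly additive.
    """
    if mask.member.shape != dmap.shape:
        raise InvalidInputError("mask does not belong to this map")
    if potency not in ("linear", "double_myopic"):
        raise InvalidInputError(f"unknown potency {potency!r}")
    if mask.n_pixels == 0:
        warnings.warn(f"region {mask.label} contains no pixels; DV = 0",
                      stacklevel=2)
        return 0.0
    g = dmap.values
    if potency == "double_myopic":
        g = np.where(g < 0, 2.0 * g, g)
    g = np.where(mask.member, g, 0.0)
    return _integrate(g, dmap.theta_x, dmap.theta_y)


def sd_defocus(dmap: DefocusMap, mask: RegionMask) -> float:
    """Sample standard deviation of defocus over the mask pixels (dioptres)."""
    if mask.n_pixels < 2:
        raise InvalidInputError(
            f"region {mask.label} has {mask.n_pixels} pixel(s); the defocus "
            "standard deviation needs at least 2"
        )
    return float(np.std(dmap.values[mask.member], ddof=1))


@dataclass
class SceneMetrics:
    """All scalar defocus summaries of one scene."""

    dv: float
    dv_2m: float
    sd_d: float
    dv_rings: dict[int, float]
    dv_2m_rings: dict[int, float]
    dv_quadrants: dict[str, float]
    dv_2m_quadrants: dict[str, float]
    mean_defocus: float
    coverage: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Flat JSON-friendly dictionary with the cohort-table column names."""
        out = {"dv": self.dv, "dv_2m": self.dv_2m, "sd_d": self.sd_d,
               "mean_defocus": self.mean_defocus, "coverage": self.coverage}
        for k, v in self.dv_rings.items():
            out[f"dv_{k}"] = v
        for k, v in self.dv_2m_rings.items():
            out[f"dv_2m_{k}"] = v
        for k, v in self.dv_quadrants.items():
            out[f"dv_{k.lower()}"] = v
        for k, v in self.dv_2m_quadrants.items():
            out[f"dv_2m_{k.lower()}"] = v
        return out


def summarize_scene(dmap: DefocusMap,
                    max_eccentricity: float = MAX_ECCENTRICITY,
                    ring_width: float = RING_WIDTH) -> SceneMetrics:
    """Reduce a defocus map to the full set of scene metrics."""
    masks = {m.label: m for m in make_masks(dmap, max_eccentricity, ring_width)}
    full = masks["FULL"]
    dv = dioptric_volume(dmap, full, "linear")
    dv2 = dioptric_volume(dmap, full, "double_myopic")
    cov = mask_coverage(dmap, full, max_eccentricity)
    ring_keys = sorted(int(lab.split("_")[1]) for lab in masks
                       if lab.startswith("RING_"))
    area = cov * np.pi * max_eccentricity**2
    return SceneMetrics(
        dv=dv,
        dv_2m=dv2,
        sd_d=sd_defocus(dmap, full),
        dv_rings={k: dioptric_volume(dmap, masks[f"RING_{k}"], "linear")
                  for k in ring_keys},
        dv_2m_rings={k: dioptric_volume(dmap, masks[f"RING_{k}"], "double_myopic")
                     for k in ring_keys},
        dv_quadrants={q: dioptric_volume(dmap, masks[f"QUAD_{q}"], "linear")
                      for q in QUADRANT_LABELS},
        dv_2m_quadrants={q: dioptric_volume(dmap, masks[f"QUAD_{q}"],
                                            "double_myopic")
                         for q in QUADRANT_LABELS},
        mean_defocus=dv / area if area > 0 else 0.0,
        coverage=cov,
        provenance=dict(dmap.provenance),
    )
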
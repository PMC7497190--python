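"""Synthetic desk scenes and synthetic progression cohorts.

The renderer ray-casts ideal planar surfaces through the pinhole camera to
produce the kind of depth frames a time-of-flight camera records when placed
0.50 m behind a child's eye, looking at a book on an inclined desk: an
inclined desk plane passing through the on-axis book point, a fronto-parallel
back wall, optional rectangular clutter at fixed distances, and an optional
window region emitting no depth return.  Depth is the perpendicular (z-axis)
distance, the convention of such devices; per-frame additive Gaussian noise
exercises frame averaging.

The cohort generator draws per-child covariates from distributions matched to
a 1-year childhood myopia-progression cohort (n = 50, age 9.3 +/- 1.2 years,
baseline spherical equivalent -1.51 +/- 2.02 D, progression -0.56 +/- 0.45 D)
and produces the refraction change from a linear generative model

    delta_m = b0 + b_age * age + b_m * M + b_dv * tDV20 + eps

in which only age, baseline refraction and the (rank-normalised) para-central
15-20 deg dioptric volume carry signal; every other generated covariate is
null, which gives backward stepwise selection something to correctly discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camera import CameraModel
from .depth import DEFAULT_MAX_RANGE, DepthFrame
from .exceptions import InvalidConfigurationError
from .stats import two_step_transform

#: (row_start, row_stop, col_start, col_stop), half-open pixel rectangle.
PixelRect = tuple[int, int, int, int]


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of a desk scene.

    Distances are eye-referenced metres except where noted; the camera sits
    ``camera_offset`` metres behind the eye on the line of sight, so the
    rendered (camera-referenced) depth of the on-axis book point is
    ``working_distance + camera_offset``.
    """

    working_distance: float = 0.30
    camera_offset: float = 0.50
    desk_tilt: float = 25.0          # deg from fronto-parallel; >0 tips the
                                     # upper image away from the viewer
    wall_distance: float = 2.5
    window_region: PixelRect | None = None
    clutter_objects: tuple[tuple[PixelRect, float], ...] = ()
    noise_sd: float = 0.004
    n_frames: int = 5
    max_range: float = DEFAULT_MAX_RANGE

    def __post_init__(self) -> None:
        if not 0.15 <= self.working_distance <= 1.0:
            raise InvalidConfigurationError(
                f"working distance {self.working_distance} m outside [0.15, 1.0]"
            )
        if self.camera_offset < 0:
            raise InvalidConfigurationError("camera offset must be >= 0")
        if self.n_frames < 1:
            raise InvalidConfigurationError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise InvalidConfigurationError("noise SD must be >= 0")
        for _, dist in self.clutter_objects:
            if dist <= 0:
                raise InvalidConfigurationError(
                    f"clutter distance {dist} m must be positive"
                )


def _rect_mask(shape: tuple[int, int], rect: PixelRect) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    r0, r1, c0, c1 = rect
    mask[r0:r1, c0:c1] = True
    return mask


def render_scene(spec: SceneSpec, camera: CameraModel,
                 seed: int) -> list[DepthFrame]:
    """Ray-cast the scene and return ``spec.n_frames`` noisy depth frames.

    Each pixel takes the nearest surface along its ray (desk plane, wall,
    clutter), expressed as perpendicular depth from the camera.  Window pixels
    and surfaces beyond ``spec.max_range`` carry the invalid sentinel.
    Identical seeds reproduce identical frames.
    """
    rng = np.random.default_rng(seed)
    theta_x, theta_y = camera.pixel_angles()
    tx = np.tan(np.radians(theta_x))[np.newaxis, :]
    ty = np.tan(np.radians(theta_y))[:, np.newaxis]
    shape = (camera.height, camera.width)

    d0 = spec.working_distance + spec.camera_offset
    # desk plane through the on-axis book point, tipped about the horizontal:
    # z = d0 + tan(tilt) * y, ray (x, y, z) = s * (tx, ty, 1) => perpendicular
    # depth s = d0 / (1 - tan(tilt) * ty) where the denominator is positive
    ta = np.tan(np.radians(spec.desk_tilt))
    denom = 1.0 - ta * ty
    with np.errstate(divide="ignore"):
        desk = np.where(denom > 1e-9, d0 / np.where(denom > 1e-9, denom, 1.0),
                        np.inf)
    desk = np.broadcast_to(desk, shape)

    wall = np.full(shape, spec.wall_distance + spec.camera_offset)
    depth = np.minimum(desk, wall)
    for rect, dist in spec.clutter_objects:
        cand = np.where(_rect_mask(shape, rect),
                        dist + spec.camera_offset, np.inf)
        depth = np.minimum(depth, cand)

    window = (_rect_mask(shape, spec.window_region)
              if spec.window_region is not None
              else np.zeros(shape, dtype=bool))

    frames = []
    for _ in range(spec.n_frames):
        d = depth.copy()
        if spec.noise_sd > 0:
            d = d + rng.normal(0.0, spec.noise_sd, size=shape)
        valid = ~window & np.isfinite(d) & (d > 0) & (d <= spec.max_range)
        frames.append(DepthFrame(depth=np.where(valid, d, 0.0), valid=valid))
    return frames


# -- synthetic cohorts ------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic progression cohort.

    ``coefficients`` holds the linear model for the 1-year refraction change:
    intercept (D), age slope (D/year), baseline-M slope (D/D), tDV20 slope
    (D per transformed D-deg^2), and the residual SD (D).  Covariate
    distribution parameters default to the reference cohort descriptives.
    """

    n_subjects: int = 50
    seed: int = 0
    coefficients: dict = field(default_factory=lambda: {
        "intercept": -1.49, "age": 0.12, "baseline_m": 0.05,
        "tdv20": -0.18, "residual_sd": 0.36,
    })
    age_mean: float = 9.3
    age_sd: float = 1.2
    age_range: tuple[float, float] = (7.0, 12.0)
    baseline_m_mean: float = -1.51
    baseline_m_sd: float = 2.02
    working_distance_mean: float = 0.297
    working_distance_sd: float = 0.06
    desk_time_log_median: float = 2.0     # h/day
    desk_time_log_sigma: float = 0.7
    outdoor_time_log_median: float = 2.0  # h/week
    outdoor_time_log_sigma: float = 1.0
    home_size_props: tuple[float, float, float] = (0.32, 0.34, 0.34)
    home_size_ranges: tuple = ((297.0, 500.0), (503.0, 602.0), (614.0, 1400.0))
    parental_myopia_probs: tuple[float, float, float] = (0.12, 0.42, 0.46)

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise InvalidConfigurationError("n_subjects must be >= 10")
        if self.coefficients.get("residual_sd", 0.0) < 0:
            raise InvalidConfigurationError("residual SD must be >= 0")
        for name, props in (("home_size_props", self.home_size_props),
                            ("parental_myopia_probs",
                             self.parental_myopia_probs)):
            if abs(sum(props) - 1.0) > 1e-9:
                raise InvalidConfigurationError(f"{name} must sum to 1")


_RING_KEYS = (5, 10, 15, 20, 25, 30)
_QUAD_KEYS = ("r", "u", "l", "d")

# shifted-lognormal shape of the regional dioptric volumes: dv = a*exp(s*z)+c.
# The 15-20 deg ring is scaled so SD(tDV20) ~= 1.07 D-deg^2, matching the
# reference cohort's standardized effect; other rings are smaller and null.
_RING_SHAPES = {k: (0.30, 0.9, -0.15) for k in _RING_KEYS}
_RING_SHAPES[20] = (0.64, 0.9, -0.34)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table with the analysis-ready column schema.

    Identical specs (including seed) reproduce byte-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    coef = spec.coefficients

    age = rng.normal(spec.age_mean, spec.age_sd, n)
    baseline_m = rng.normal(spec.baseline_m_mean, spec.baseline_m_sd, n)
    cylinder = -np.abs(rng.normal(0.0, 0.5, n))
    sphere = baseline_m - cylinder / 2.0
    working = rng.normal(spec.working_distance_mean,
                         spec.working_distance_sd, n).clip(0.15, 1.0)
    desk = np.exp(rng.normal(np.log(spec.desk_time_log_median),
                             spec.desk_time_log_sigma, n))
    outdoor = np.exp(rng.normal(np.log(spec.outdoor_time_log_median),
                                spec.outdoor_time_log_sigma, n))
    hs_group = rng.choice(3, size=n, p=spec.home_size_props)
    lo = np.array([spec.home_size_ranges[g][0] for g in hs_group])
    hi = np.array([spec.home_size_ranges[g][1] for g in hs_group])
    home_size = rng.uniform(lo, hi)
    parental = rng.choice(3, size=n, p=spec.parental_myopia_probs)

    rings = {}
    rings_2m = {}
    for k in _RING_KEYS:
        a, s, c = _RING_SHAPES[k]
        z = rng.normal(0.0, 1.0, n)
        rings[k] = a * np.exp(s * z) + c
        rings_2m[k] = rings[k] - 0.05 * np.exp(rng.normal(0.0, 0.7, n))
    dv = sum(rings.values())
    dv_2m = sum(rings_2m.values())
    quad_w = rng.dirichlet(np.full(4, 8.0), size=n)
    quads = {q: dv * quad_w[:, i] for i, q in enumerate(_QUAD_KEYS)}
    quad_w2 = rng.dirichlet(np.full(4, 8.0), size=n)
    quads_2m = {q: dv_2m * quad_w2[:, i] for i, q in enumerate(_QUAD_KEYS)}
    sd_d = np.exp(rng.normal(np.log(0.49), 0.6, n))

    tdv20 = two_step_transform(rings[20])
    eps = (rng.normal(0.0, coef["residual_sd"], n)
           if coef["residual_sd"] > 0 else np.zeros(n))
    delta_m = (coef["intercept"] + coef["age"] * age
               + coef["baseline_m"] * baseline_m
               + coef["tdv20"] * tdv20 + eps)

    table = {
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "age": age,
        "sphere": sphere,
        "cylinder": cylinder,
        "baseline_m": baseline_m,
        "delta_m": delta_m,
        "followup_m": baseline_m + delta_m,
        "working_distance": working,
        "desk_time": desk,
        "outdoor_time": outdoor,
        "home_size": home_size,
        "parental_myopia": parental,
        "dv": dv,
        "dv_2m": dv_2m,
        "sd_d": sd_d,
    }
    for k in _RING_KEYS:
        table[f"dv_{k}"] = rings[k]
    for k in _RING_KEYS:
        table[f"dv_2m_{k}"] = rings_2m[k]
    for q in _QUAD_KEYS:
        table[f"dv_{q}"] = quads[q]
    for q in _QUAD_KEYS:
        table[f"dv_2m_{q}"] = quads_2m[q]
    return pd.DataFrame(table)
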
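"""End-to-end pipelines: depth frames -> scene metrics, cohort -> statistics.

Both entry points are deterministic for a fixed configuration and seed and
embed the fully resolved configuration plus the package version in their
output documents.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .camera import CameraModel
from .depth import (DEFAULT_MAX_RANGE, DepthFrame, apply_offset,
                    average_frames, calibrate, read_depth_frame)
from .defocus import to_defocus
from .exceptions import (InsufficientGroupError,
                         InvalidConfigurationError, SchemaError)
from .metrics import SceneMetrics, summarize_scene
from .stats import (group_comparisons, spearman_partial, spherical_equivalent,
                    stepwise_backward, two_step_transform)

log = logging.getLogger("scenedefocus")

RING_KEYS = (5, 10, 15, 20, 25, 30)
QUAD_KEYS = ("r", "u", "l", "d")

#: columns a cohort table must provide for the full analysis
REQUIRED_COLUMNS = (
    ("age", "baseline_m", "delta_m", "working_distance", "desk_time",
     "outdoor_time", "home_size", "parental_myopia", "dv", "dv_2m", "sd_d")
    + tuple(f"dv_{k}" for k in RING_KEYS)
    + tuple(f"dv_2m_{k}" for k in RING_KEYS)
    + tuple(f"dv_{q}" for q in QUAD_KEYS)
    + tuple(f"dv_2m_{q}" for q in QUAD_KEYS)
)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for both pipeline stages."""

    camera: CameraModel = field(default_factory=CameraModel)
    max_range: float = DEFAULT_MAX_RANGE
    nominal_camera_offset: float = 0.50   # m, fallback when centre unreadable
    max_eccentricity: float = 30.0
    ring_width: float = 5.0
    blom_c: float = 0.375
    p_threshold: float = 0.05
    desk_cut_hours: float = 2.0           # h/day, Low/High split
    outdoor_cut_hours: float = 2.0        # h/week, Low/High split
    home_size_cuts: tuple[float, float] | None = None  # ft^2; None = tertiles
    equal_var_t: bool = True
    decimals: int = 2

    def __post_init__(self) -> None:
        ratio = self.max_eccentricity / self.ring_width
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidConfigurationError(
                "ring width must divide the maximum eccentricity"
            )
        if not 0 < self.p_threshold < 1:
            raise InvalidConfigurationError("p threshold must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["camera"] = asdict(self.camera)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cam = d.pop("camera", None)
        if isinstance(cam, dict):
            if cam.get("principal_point") is not None:
                cam["principal_point"] = tuple(cam["principal_point"])
            camera = CameraModel(**cam)
        else:
            camera = CameraModel()
        known = {f for f in cls.__dataclass_fields__ if f != "camera"}
        d = {k: v for k, v in d.items() if k in known}
        if d.get("home_size_cuts") is not None:
            d["home_size_cuts"] = tuple(d["home_size_cuts"])
        return cls(camera=camera, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# -- scene pipeline ---------------------------------------------------------


def run_scene_pipeline(frames, measured_distance: float,
                       config: PipelineConfig | None = None) -> SceneMetrics:
    """Average, calibrate and summarise one scene.

    ``frames`` may be paths to depth files or :class:`DepthFrame` objects.
    If the centre pixel is unreadable in every frame the stage falls back to
    the configured nominal camera offset and sets the target vergence from
    the tape-measured distance; this is recorded in the provenance.
    """
    config = config or PipelineConfig()
    loaded = [f if isinstance(f, DepthFrame)
              else read_depth_frame(f, config.max_range) for f in frames]
    dmap = average_frames(loaded)
    if dmap.centre_valid:
        dmap = calibrate(dmap, measured_distance)
        defocus = to_defocus(dmap, config.camera)
        fallback = False
    else:
        log.warning("centre pixel unreadable; assuming nominal camera offset "
                    "%.2f m and tape-measured target distance",
                    config.nominal_camera_offset)
        dmap = apply_offset(dmap, config.nominal_camera_offset)
        defocus = to_defocus(dmap, config.camera,
                             target_vergence=1.0 / measured_distance)
        fallback = True
    metrics = summarize_scene(defocus, config.max_eccentricity,
                              config.ring_width)
    metrics.provenance["measured_distance_m"] = measured_distance
    metrics.provenance["centre_fallback"] = fallback
    return metrics


def scene_metrics_document(metrics: SceneMetrics,
                           config: PipelineConfig) -> dict:
    return {"version": __version__, "config": config.to_dict(),
            "metrics": metrics.to_dict(), "provenance": metrics.provenance}


# -- cohort pipeline --------------------------------------------------------


def _validate_schema(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    # baseline M may instead be derivable from sphere + cylinder
    if "baseline_m" in missing and {"sphere", "cylinder"} <= set(df.columns):
        missing.remove("baseline_m")
    if "delta_m" in missing and "followup_m" in df.columns:
        missing.remove("delta_m")
    if missing:
        raise SchemaError(missing)


def prepare_cohort(df: pd.DataFrame,
                   config: PipelineConfig) -> pd.DataFrame:
    """Validate the schema and derive analysis columns.

    Adds (where absent) the spherical equivalent, the refraction change, the
    ranked home-size group (tertiles by default, 16/17/17-style split sizes),
    Low/High exposure indicators, indicator codings, and the rank-normalised
    (two-step transformed) regional metrics ``tdv_*`` / ``tsd_d``.
    """
    _validate_schema(df)
    df = df.copy()
    if "baseline_m" not in df.columns:
        df["baseline_m"] = spherical_equivalent(df["sphere"], df["cylinder"])
    if "delta_m" not in df.columns:
        df["delta_m"] = df["followup_m"] - df["baseline_m"]

    if config.home_size_cuts is not None:
        c1, c2 = config.home_size_cuts
        df["home_size_group"] = np.where(
            df["home_size"] <= c1, "Small",
            np.where(df["home_size"] <= c2, "Medium", "Large"))
    else:
        n = len(df)
        k, rem = divmod(n, 3)
        sizes = [k, k, k]
        for i in range(rem):
            sizes[-(i + 1)] += 1
        order = np.argsort(df["home_size"].to_numpy(), kind="stable")
        labels = np.empty(n, dtype=object)
        start = 0
        for lab, sz in zip(("Small", "Medium", "Large"), sizes):
            labels[order[start:start + sz]] = lab
            start += sz
        df["home_size_group"] = labels

    df["desk_high"] = (df["desk_time"] >= config.desk_cut_hours).astype(int)
    df["outdoor_high"] = (df["outdoor_time"]
                          >= config.outdoor_cut_hours).astype(int)
    df["home_medium"] = (df["home_size_group"] == "Medium").astype(int)
    df["home_large"] = (df["home_size_group"] == "Large").astype(int)
    df["pm_one"] = (df["parental_myopia"] == 1).astype(int)
    df["pm_two"] = (df["parental_myopia"] == 2).astype(int)

    for col in ([f"dv_{k}" for k in RING_KEYS]
                + [f"dv_2m_{k}" for k in RING_KEYS]
                + [f"dv_{q}" for q in QUAD_KEYS]
                + [f"dv_2m_{q}" for q in QUAD_KEYS]
                + ["sd_d"]):
        df[f"t{col}"] = two_step_transform(df[col].to_numpy(), c=config.blom_c)
    return df


_BASE_PREDICTORS = ["age", "baseline_m", "working_distance", "desk_high",
                    "outdoor_high", "pm_one", "pm_two", "home_medium",
                    "home_large", "tsd_d"]

REGRESSION_BLOCKS = {
    "ring_1x": [f"tdv_{k}" for k in RING_KEYS],
    "quadrant_1x": [f"tdv_{q}" for q in QUAD_KEYS],
    "ring_2m": [f"tdv_2m_{k}" for k in RING_KEYS],
    "quadrant_2m": [f"tdv_2m_{q}" for q in QUAD_KEYS],
}


def regression_block(df: pd.DataFrame, block: str,
                     config: PipelineConfig | None = None):
    """Fit one backward-stepwise block (ring/quadrant x potency)."""
    config = config or PipelineConfig()
    predictors = _BASE_PREDICTORS + REGRESSION_BLOCKS[block]
    return stepwise_backward(df[predictors], df["delta_m"],
                             config.p_threshold)


def run_cohort_pipeline(cohort, config: PipelineConfig | None = None) -> dict:
    """Full statistical analysis of a cohort table (path or DataFrame)."""
    config = config or PipelineConfig()
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    df = prepare_cohort(cohort, config)
    dm, m = df["delta_m"].to_numpy(), df["baseline_m"].to_numpy()

    correlations = {}
    for col in ("dv", "dv_2m", "sd_d"):
        r = spearman_partial(df[col].to_numpy(), dm, control=m,
                             control_label="baseline_m")
        correlations[col] = {"rho": r.rho, "p": r.p_value, "n": r.n,
                             "control": r.control}
    for col in ([f"dv_{k}" for k in RING_KEYS]
                + [f"dv_2m_{k}" for k in RING_KEYS]
                + [f"dv_{q}" for q in QUAD_KEYS]
                + [f"dv_2m_{q}" for q in QUAD_KEYS]):
        r = spearman_partial(df[col].to_numpy(), dm)
        correlations[col] = {"rho": r.rho, "p": r.p_value, "n": r.n,
                             "control": None}

    regressions = {name: regression_block(df, name, config).to_dict()
                   for name in REGRESSION_BLOCKS}
    try:
        groups = group_comparisons(df, desk_cut=config.desk_cut_hours,
                                   outdoor_cut=config.outdoor_cut_hours,
                                   equal_var=config.equal_var_t)
    except InsufficientGroupError as err:
        # a degenerate grouping voids the univariate section, not the document
        log.warning("group comparisons skipped: %s", err)
        groups = {"error": str(err)}
    descr = {
        "n": int(len(df)),
        "age": {"mean": float(df["age"].mean()),
                "sd": float(df["age"].std(ddof=1))},
        "baseline_m": {"mean": float(df["baseline_m"].mean()),
                       "sd": float(df["baseline_m"].std(ddof=1))},
        "delta_m": {"mean": float(dm.mean()),
                    "sd": float(dm.std(ddof=1))},
        "working_distance": {"mean": float(df["working_distance"].mean()),
                             "sd": float(df["working_distance"].std(ddof=1))},
        "dv": _median_iqr(df["dv"]),
        "dv_2m": _median_iqr(df["dv_2m"]),
        "sd_d": _median_iqr(df["sd_d"]),
    }
    return {"version": __version__, "config": config.to_dict(),
            "descriptives": descr, "correlations": correlations,
            "regressions": regressions, "group_comparisons": groups}


def _median_iqr(s: pd.Series) -> dict:
    q1, med, q3 = np.percentile(s, [25, 50, 75])
    return {"median": float(med), "iqr": [float(q1), float(q3)]}


# -- reporting --------------------------------------------------------------


def render_report(results: dict, decimals: int = 2) -> str:
    """Human-readable summary of a cohort-analysis document."""
    f = f"{{:.{decimals}f}}"

    def fmt(x):
        return f.format(x)

    d = results["descriptives"]
    lines = [
        f"scenedefocus cohort analysis (v{results['version']})",
        f"n = {d['n']}; age {fmt(d['age']['mean'])} ± {fmt(d['age']['sd'])} y; "
        f"baseline M {fmt(d['baseline_m']['mean'])} ± "
        f"{fmt(d['baseline_m']['sd'])} D; "
        f"ΔM {fmt(d['delta_m']['mean'])} ± {fmt(d['delta_m']['sd'])} D",
        "",
        "Partial Spearman correlations with ΔM (controlling baseline M):",
    ]
    for col in ("dv", "dv_2m", "sd_d"):
        c = results["correlations"][col]
        lines.append(f"  {col:8s} rho = {fmt(c['rho'])}, p = {c['p']:.3f}")
    lines.append("")
    for name, block in results["regressions"].items():
        lines.append(f"Stepwise regression [{name}]: adj R² = "
                     f"{fmt(block['adj_r2'])}, F({block['df'][0]},"
                     f"{block['df'][1]}) = {fmt(block['f'])}, "
                     f"p = {block['f_p']:.3g}")
        for term, row in block["retained"].items():
            lines.append(
                f"  {term:14s} B = {fmt(row['b'])} "
                f"[{fmt(row['ci95'][0])}, {fmt(row['ci95'][1])}], "
                f"std B = {fmt(row['std_b'])}, p = {row['p']:.3f}, "
                f"VIF = {fmt(row['vif'])}")
        lines.append("")
    g = results["group_comparisons"]
    a = g["home_size"]["anova_delta_m"]
    lines.append(f"ΔM by home size: ANOVA F({a['df'][0]},{a['df'][1]}) = "
                 f"{fmt(a['F'])}, p = {a['p']:.3f}")
    for lab, s in g["home_size"]["groups"].items():
        lines.append(f"  {lab:7s} n = {s['n']:3d}  ΔM = {fmt(s['mean'])} ± "
                     f"{fmt(s['sd'])} D")
    for name, lab in (("desk_time", "desk time"),
                      ("outdoor_time", "outdoor time")):
        t = g[name]["t_test"]
        lines.append(
            f"ΔM Low vs High {lab}: t({t['df']}) = {fmt(t['t'])}, "
            f"p = {t['p']:.3f} "
            f"(Low {fmt(g[name]['low']['mean'])} ± {fmt(g[name]['low']['sd'])}"
            f", High {fmt(g[name]['high']['mean'])} ± "
            f"{fmt(g[name]['high']['sd'])})")
    return "\n".join(lines) + "\n"


def write_json(document: dict, path) -> None:
    """Serialise a results document with stable key order and native floats."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(document, indent=2, default=_default)
                          + "\n")
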
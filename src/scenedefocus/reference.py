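"""Published subgroup summaries used as consistency-check inputs.

These are the printed per-subgroup sample sizes and 1-year refraction-change
means/SDs (dioptres) from a 50-child myopia-progression cohort.  They serve
as reference inputs for internal arithmetic consistency checks: within each
partition the n-weighted mean of the subgroup means must reproduce the
overall mean change of -0.56 D.
"""

from __future__ import annotations

#: overall 1-year change in spherical equivalent, D (mean, SD, n)
OVERALL = {"n": 50, "mean": -0.56, "sd": 0.45}

#: subgroup partitions: label -> (n, mean delta-M, SD)
SUBGROUPS: dict[str, dict[str, tuple[int, float, float]]] = {
    "home_size": {
        "Small": (16, -0.87, 0.52),
        "Medium": (17, -0.46, 0.32),
        "Large": (17, -0.38, 0.35),
    },
    "parental_myopia": {
        "None": (6, -0.23, 0.43),
        "One": (21, -0.67, 0.52),
        "Two": (23, -0.55, 0.35),
    },
    "desk_time": {
        "Low": (21, -0.50, 0.47),
        "High": (29, -0.61, 0.43),
    },
    "outdoor_time": {
        "Low": (24, -0.70, 0.47),
        "High": (26, -0.44, 0.40),
    },
}


def weighted_mean(partition: str) -> float:
    """n-weighted mean of the subgroup means for one partition of the cohort."""
    rows = SUBGROUPS[partition].values()
    total_n = sum(n for n, _, _ in rows)
    return sum(n * mean for n, mean, _ in rows) / total_n
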
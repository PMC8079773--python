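"""Per-scan MR image quality metrics and cohort comparison.

Metrics fall into four groups: resolution (voxel dimensions, slice
thickness — from the grid geometry / metadata), acquisition (repetition
and echo time — passed through from metadata), foreground (mean, range
and signal-to-noise ratio over an Otsu-thresholded foreground) and
artifacts (the entropy focus criterion, a blur/motion surrogate).

The entropy focus criterion is the Shannon entropy of the normalized
voxel magnitudes divided by its maximum (the log of the voxel count),
so it lies in [0, 1]: 0 when all signal sits in a single voxel, 1 for a
perfectly uniform magnitude image, and it is invariant to global
intensity scaling.

Cohorts are compared metric-by-metric with the Kruskal-Wallis rank
test.  Because a rank test addresses distributional location rather
than spread, a second mode applies the same test to absolute deviations
from the cohort median — a rank-based dispersion comparison; both
readings are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .grids import VoxelGrid

FOREGROUND_METRICS = ("foreground_mean", "foreground_range", "snr")
ARTIFACT_METRICS = ("efc",)
RESOLUTION_METRICS = ("voxel_dim_x", "voxel_dim_y", "slice_thickness")
ACQUISITION_METRICS = ("repetition_time", "echo_time")


@dataclass(frozen=True)
class QualityMetrics:
    scan_id: str
    cohort: str
    values: dict[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()


def entropy_focus_criterion(values: np.ndarray) -> float:
    """Normalized Shannon entropy of voxel magnitudes, in [0, 1]."""
    mag = np.abs(np.asarray(values, dtype=np.float64)).ravel()
    total = mag.sum()
    if total <= 0:
        return 0.0
    p = mag / total
    p = p[p > 0]
    if p.size <= 1:
        return 0.0
    ent = float(-(p * np.log(p)).sum())
    return ent / np.log(mag.size)


def compute_quality(grid: VoxelGrid, metadata: dict | None = None, scan_id: str = "", cohort: str = "") -> QualityMetrics:
    """Quality metrics of one scan; metadata supplies TR/TE when known."""
    metadata = metadata or {}
    vals = grid.values.astype(np.float64)
    flags: list[str] = []

    if np.all(vals == vals.flat[0]):
        raise ValueError("constant image: foreground detection is impossible")
    thr = threshold_otsu(vals)
    fg = vals > thr
    if not fg.any():
        raise ValueError("empty foreground after Otsu thresholding")
    bg = vals[~fg]
    fg_vals = vals[fg]

    bg_sd = float(bg.std()) if bg.size else 0.0
    if bg_sd > 0:
        snr = float(fg_vals.mean() / bg_sd)
    else:
        snr = float("inf")
        flags.append("snr_undefined_zero_background_sd")
        snr = 0.0

    metrics = {
        "voxel_dim_x": grid.spacing[0],
        "voxel_dim_y": grid.spacing[1],
        "slice_thickness": grid.spacing[2],
        "repetition_time": float(metadata.get("repetition_time", np.nan)),
        "echo_time": float(metadata.get("echo_time", np.nan)),
        "foreground_mean": float(fg_vals.mean()),
        "foreground_range": float(fg_vals.max() - fg_vals.min()),
        "snr": snr,
        "efc": entropy_focus_criterion(vals),
    }
    return QualityMetrics(scan_id, cohort, metrics, tuple(flags))


def metrics_table(metrics: list[QualityMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append({"scan_id": m.scan_id, "cohort": m.cohort, **m.values})
    return pd.DataFrame(rows).set_index("scan_id")


def compare_cohorts(metrics_a: list[QualityMetrics], metrics_b: list[QualityMetrics], dispersion: bool = False) -> pd.DataFrame:
    """Per-metric two-sample Kruskal-Wallis comparison of two cohorts.

    With ``dispersion=True`` the test is applied to absolute deviations
    from each cohort's median (a rank-based spread comparison).  Returns
    a table with statistic, p and a significance flag at 0.05; a metric
    constant across both cohorts is flagged with p undefined.
    """
    if len(metrics_a) < 3 or len(metrics_b) < 3:
        raise ValueError("need at least 3 scans per cohort")
    ta, tb = metrics_table(metrics_a), metrics_table(metrics_b)
    rows = []
    for metric in ta.columns:
        if metric == "cohort":
            continue
        a = ta[metric].to_numpy(dtype=float)
        b = tb[metric].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        row = {"metric": metric, "statistic": np.nan, "p": np.nan, "significant": False, "flag": None}
        if len(a) < 3 or len(b) < 3:
            row["flag"] = "insufficient_data"
            rows.append(row)
            continue
        if dispersion:
            a = np.abs(a - np.median(a))
            b = np.abs(b - np.median(b))
        if np.all(np.concatenate([a, b]) == a[0]):
            row["flag"] = "constant_metric"
            rows.append(row)
            continue
        stat, p = stats.kruskal(a, b)
        row.update(statistic=float(stat), p=float(p), significant=bool(p < 0.05))
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
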
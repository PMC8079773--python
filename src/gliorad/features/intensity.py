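"""First-order intensity statistics over a VOI.

Statistics use population (biased) moment conventions; kurtosis is
excess kurtosis (0 for a normal distribution).  Histogram entropy and
energy are computed on the discretized grey-level histogram of the VOI.
The intensity-volume-histogram features ``enhancing_tumor_volume_X``
give the fraction of VOI voxels whose intensity lies strictly above
X% of the in-VOI intensity range.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..grids import VoiMask, VoxelGrid
from ..preprocess import DiscretizedVolume

ETV_FRACTIONS = (30, 40, 70)


def compute_intensity(grid: VoxelGrid, mask: VoiMask, dv: DiscretizedVolume | None = None):
    """The 19 intensity features. Returns ``(values, flags)``.

    ``dv`` supplies the discretized volume used for the histogram
    features; when omitted they are computed on a 32-level fixed-bin-
    number discretization of the VOI.
    """
    grid.require_aligned(mask, "grid/mask")
    x = grid.values[mask.values].astype(np.float64)
    if x.size == 0:
        raise ValueError("empty mask")
    flags: set[str] = set()
    out: dict[str, float] = {}

    mean = float(x.mean())
    var = float(x.var())  # population convention
    out["mean"] = mean
    out["variance"] = var
    if var > 0:
        out["skewness"] = float(stats.skew(x, bias=True))
        out["kurtosis"] = float(stats.kurtosis(x, fisher=True, bias=True))
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
        flags.update(("skewness", "kurtosis"))
    out["median"] = float(np.median(x))
    out["minimum"] = float(x.min())
    out["maximum"] = float(x.max())
    out["range"] = out["maximum"] - out["minimum"]
    p10, p90 = np.percentile(x, (10, 90))
    out["percentile_10"] = float(p10)
    out["percentile_90"] = float(p90)
    if var > 0 and mean != 0:
        out["coefficient_of_variation"] = float(np.sqrt(var) / mean)
    else:
        out["coefficient_of_variation"] = 0.0
        flags.add("coefficient_of_variation")
    core = x[(x >= p10) & (x <= p90)]
    out["robust_mean_absolute_deviation"] = float(np.abs(core - core.mean()).mean())
    out["energy"] = float((x**2).sum())
    out["root_mean_square"] = float(np.sqrt((x**2).mean()))

    if dv is None:
        from ..preprocess import discretize_fixed_bin_number

        dv = discretize_fixed_bin_number(grid, mask, 32)
    levels = dv.levels[dv.mask]
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / levels.size
    out["histogram_entropy"] = float(-(p * np.log2(p)).sum())
    out["histogram_energy"] = float((p**2).sum())

    rng = out["range"]
    for frac in ETV_FRACTIONS:
        name = f"enhancing_tumor_volume_{frac}"
        if rng > 0:
            cut = out["minimum"] + frac / 100.0 * rng
            out[name] = float((x > cut).mean())
        else:
            out[name] = 0.0
            flags.add(name)

    return {"intensity_" + k: v for k, v in out.items()}, {"intensity_" + k for k in flags}
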
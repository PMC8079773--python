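"""Texture features computed from the texture matrices.

Feature definitions follow the standardized texture descriptors used in
quantitative radiomics.  Conventions for degenerate inputs (applied
identically everywhere, and surfaced via the returned flag set rather
than silent NaN):

* entropies use base-2 logarithms and skip zero-probability cells;
* a matrix with no tallied entries (e.g. co-occurrence of a single
  voxel) yields 0 for every feature of its family, flagged degenerate;
* co-occurrence correlation is 0 (flagged) when the marginal variance
  vanishes (single grey level); the maximal correlation coefficient is
  1 in that case;
* NGTDM coarseness is capped at 1e6 when the weighted difference sum is
  zero (constant volume); busyness, contrast and strength are 0 there.
"""

from __future__ import annotations

import numpy as np

from .matrices import DIRECTIONS, TextureMatrices

COARSENESS_CAP = 1e6


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(counts: np.ndarray, with_mcc: bool = False):
    """Features of one (symmetric) co-occurrence count matrix."""
    flags: set[str] = set()
    G = counts.shape[0]
    total = counts.sum()
    out: dict[str, float] = {}
    if total == 0:
        zero = dict.fromkeys(
            (
                "joint_maximum joint_average joint_variance joint_entropy "
                "difference_average difference_variance difference_entropy "
                "sum_average sum_variance sum_entropy angular_second_moment "
                "contrast dissimilarity inverse_difference "
                "inverse_difference_normalised inverse_difference_moment "
                "inverse_difference_moment_normalised inverse_variance "
                "correlation autocorrelation cluster_tendency cluster_shade "
                "cluster_prominence information_correlation_1 "
                "information_correlation_2"
            ).split(),
            0.0,
        )
        if with_mcc:
            zero["maximal_correlation_coefficient"] = 0.0
        return zero, set(zero)

    p = counts.astype(np.float64) / total
    i = np.arange(1, G + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((ii * p).sum())

    out["joint_maximum"] = float(p.max())
    out["joint_average"] = mu
    out["joint_variance"] = float(((ii - mu) ** 2 * p).sum())
    out["joint_entropy"] = _entropy(p.ravel())

    k_diff = np.abs(ii - jj)
    p_diff = np.array([p[k_diff == k].sum() for k in range(G)])
    kd = np.arange(G)
    da = float((kd * p_diff).sum())
    out["difference_average"] = da
    out["difference_variance"] = float(((kd - da) ** 2 * p_diff).sum())
    out["difference_entropy"] = _entropy(p_diff)

    k_sum = ii + jj
    ks = np.arange(2, 2 * G + 1)
    p_sum = np.array([p[k_sum == k].sum() for k in ks])
    sa = float((ks * p_sum).sum())
    out["sum_average"] = sa
    out["sum_variance"] = float(((ks - sa) ** 2 * p_sum).sum())
    out["sum_entropy"] = _entropy(p_sum)

    out["angular_second_moment"] = float((p**2).sum())
    out["contrast"] = float(((ii - jj) ** 2 * p).sum())
    out["dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    out["inverse_difference"] = float((p / (1 + np.abs(ii - jj))).sum())
    out["inverse_difference_normalised"] = float((p / (1 + np.abs(ii - jj) / G)).sum())
    out["inverse_difference_moment"] = float((p / (1 + (ii - jj) ** 2)).sum())
    out["inverse_difference_moment_normalised"] = float(
        (p / (1 + (ii - jj) ** 2 / G**2)).sum()
    )
    off = ii != jj
    out["inverse_variance"] = float((p[off] / (ii[off] - jj[off]) ** 2).sum())

    var = float(((i - mu) ** 2 * px).sum())
    if var <= 0:
        out["correlation"] = 0.0
        flags.add("correlation")
    else:
        out["correlation"] = float(((ii - mu) * (jj - mu) * p).sum() / var)
    out["autocorrelation"] = float((ii * jj * p).sum())
    out["cluster_tendency"] = float(((ii + jj - 2 * mu) ** 2 * p).sum())
    out["cluster_shade"] = float(((ii + jj - 2 * mu) ** 3 * p).sum())
    out["cluster_prominence"] = float(((ii + jj - 2 * mu) ** 4 * p).sum())

    hxy = out["joint_entropy"]
    hx = _entropy(px)
    pxpy = np.outer(px, px)
    sel = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[sel] * np.log2(pxpy[sel])).sum())
    sel2 = pxpy > 0
    hxy2 = float(-(pxpy[sel2] * np.log2(pxpy[sel2])).sum())
    if hx <= 0:
        out["information_correlation_1"] = 0.0
        flags.add("information_correlation_1")
    else:
        out["information_correlation_1"] = (hxy - hxy1) / hx
    out["information_correlation_2"] = float(np.sqrt(max(0.0, 1.0 - 2.0 ** (-2 * (hxy2 - hxy)))))

    if with_mcc:
        nz = px > 0
        if nz.sum() <= 1:
            out["maximal_correlation_coefficient"] = 1.0
            flags.add("maximal_correlation_coefficient")
        else:
            pr = p[np.ix_(nz, nz)]
            pxr = px[nz]
            q = np.einsum("ik,jk->ij", pr / pxr[:, None], pr / pxr[None, :])
            eig = np.sort(np.real(np.linalg.eigvals(q)))
            out["maximal_correlation_coefficient"] = float(np.sqrt(max(0.0, eig[-2])))
    return out, flags


def _gl_j_matrix_features(matrix: np.ndarray, n_denom: float, names: tuple[str, ...]):
    """Shared template for run-length / size-zone / distance-zone /
    dependence matrices: rows are grey levels, columns a size-like index j.

    ``names`` supplies the 16 family-specific feature names in the fixed
    template order (low-j, high-j, low-g, high-g, the four combinations,
    grey-level non-uniformity (+normalised), j non-uniformity
    (+normalised), percentage, grey-level variance, j variance,
    j entropy); a 17th name, if present, is the energy Sum p^2.
    """
    flags: set[str] = set()
    Ns = matrix.sum()
    if Ns == 0:
        return dict.fromkeys(names, 0.0), set(names)
    G, J = matrix.shape
    g = np.arange(1, G + 1, dtype=np.float64)
    j = np.arange(1, J + 1, dtype=np.float64)
    s = matrix.astype(np.float64)
    sg = s.sum(axis=1)
    sj = s.sum(axis=0)
    p = s / Ns
    gg, jjj = np.meshgrid(g, j, indexing="ij")

    vals = [
        float((sj / j**2).sum() / Ns),
        float((sj * j**2).sum() / Ns),
        float((sg / g**2).sum() / Ns),
        float((sg * g**2).sum() / Ns),
        float((s / (gg**2 * jjj**2)).sum() / Ns),
        float((s * gg**2 / jjj**2).sum() / Ns),
        float((s * jjj**2 / gg**2).sum() / Ns),
        float((s * gg**2 * jjj**2).sum() / Ns),
        float((sg**2).sum() / Ns),
        float((sg**2).sum() / Ns**2),
        float((sj**2).sum() / Ns),
        float((sj**2).sum() / Ns**2),
        float(Ns / n_denom),
        float((p.sum(axis=1) * g**2).sum() - ((p.sum(axis=1) * g).sum()) ** 2),
        float((p.sum(axis=0) * j**2).sum() - ((p.sum(axis=0) * j).sum()) ** 2),
        _entropy(p.ravel()),
    ]
    if len(names) == 17:
        vals.append(float((p**2).sum()))
    return dict(zip(names, vals)), flags


def ngtdm_features(s: np.ndarray, n: np.ndarray):
    flags: set[str] = set()
    Nv = n.sum()
    out = dict.fromkeys(("coarseness", "contrast", "busyness", "complexity", "strength"), 0.0)
    if Nv == 0:
        return out, set(out)
    p = n.astype(np.float64) / Nv
    i = np.arange(1, len(n) + 1, dtype=np.float64)
    nz = p > 0
    Ngp = int(nz.sum())

    denom = float((p * s).sum())
    if denom <= 0:
        out["coarseness"] = COARSENESS_CAP
        flags.add("coarseness")
    else:
        out["coarseness"] = 1.0 / denom

    if Ngp > 1:
        pi, ii = p[nz], i[nz]
        diff2 = (ii[:, None] - ii[None, :]) ** 2
        out["contrast"] = float(
            (pi[:, None] * pi[None, :] * diff2).sum()
            / (Ngp * (Ngp - 1))
            * s.sum()
            / Nv
        )
        denom_b = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
        num_b = float((p * s).sum())
        out["busyness"] = num_b / denom_b if denom_b > 0 else 0.0
        si = s[nz]
        out["complexity"] = float(
            (
                np.abs(ii[:, None] - ii[None, :])
                * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                / (pi[:, None] + pi[None, :])
            ).sum()
            / Nv
        )
        ssum = float(s.sum())
        if ssum > 0:
            out["strength"] = float(
                ((pi[:, None] + pi[None, :]) * diff2).sum() / ssum
            )
        else:
            flags.add("strength")
    else:
        flags.update(("contrast", "busyness", "complexity", "strength"))
    return out, flags


_GLRLM_NAMES = (
    "short_runs_emphasis",
    "long_runs_emphasis",
    "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis",
    "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis",
    "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalised",
    "run_percentage",
    "grey_level_variance",
    "run_length_variance",
    "run_entropy",
)

_GLSZM_NAMES = (
    "small_zone_emphasis",
    "large_zone_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_zone_low_grey_level_emphasis",
    "small_zone_high_grey_level_emphasis",
    "large_zone_low_grey_level_emphasis",
    "large_zone_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalised",
    "zone_percentage",
    "grey_level_variance",
    "zone_size_variance",
    "zone_size_entropy",
)

_GLDZM_NAMES = (
    "small_distance_emphasis",
    "large_distance_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_distance_low_grey_level_emphasis",
    "small_distance_high_grey_level_emphasis",
    "large_distance_low_grey_level_emphasis",
    "large_distance_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "zone_distance_non_uniformity",
    "zone_distance_non_uniformity_normalised",
    "zone_percentage",
    "grey_level_variance",
    "zone_distance_variance",
    "zone_distance_entropy",
)

_NGLDM_NAMES = (
    "low_dependence_emphasis",
    "high_dependence_emphasis",
    "low_grey_level_count_emphasis",
    "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis",
    "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis",
    "high_dependence_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalised",
    "dependence_count_percentage",
    "grey_level_variance",
    "dependence_count_variance",
    "dependence_count_entropy",
    "dependence_count_energy",
)


def compute_texture_features(tm: TextureMatrices):
    """All 137 texture features of one VOI.

    Returns ``(values, flags)`` where flags names features whose
    degenerate convention was applied.
    """
    out: dict[str, float] = {}
    flags: set[str] = set()

    def add(prefix: str, vals: dict, fl: set) -> None:
        for k, v in vals.items():
            out[prefix + k] = v
        flags.update(prefix + k for k in fl)

    vals, fl = glcm_features(tm.glcm, with_mcc=True)
    add("glcm_", vals, fl)

    # direction-averaged variant: average feature values over directions
    # that contain at least one pair
    per_dir = [glcm_features(c, with_mcc=False) for c in tm.glcm_by_direction if c.sum() > 0]
    if per_dir:
        keys = per_dir[0][0].keys()
        avg = {k: float(np.mean([v[0][k] for v in per_dir])) for k in keys}
        fl_avg = set().union(*(v[1] for v in per_dir))
    else:
        avg, _ = glcm_features(np.zeros((tm.n_levels, tm.n_levels), dtype=np.int64))
        fl_avg = set(avg)
    add("glcm_avg_", avg, fl_avg)

    n_dirs = len(DIRECTIONS)
    vals, fl = _gl_j_matrix_features(tm.glrlm, tm.n_voxels * n_dirs, _GLRLM_NAMES)
    add("glrlm_", vals, fl)

    per_dir_r = [
        _gl_j_matrix_features(m, tm.n_voxels, _GLRLM_NAMES)
        for m in tm.glrlm_by_direction
        if m.sum() > 0
    ]
    if per_dir_r:
        avg_r = {k: float(np.mean([v[0][k] for v in per_dir_r])) for k in _GLRLM_NAMES}
        fl_r = set().union(*(v[1] for v in per_dir_r))
    else:
        avg_r = dict.fromkeys(_GLRLM_NAMES, 0.0)
        fl_r = set(_GLRLM_NAMES)
    add("glrlm_avg_", avg_r, fl_r)

    vals, fl = _gl_j_matrix_features(tm.glszm, tm.n_voxels, _GLSZM_NAMES)
    add("glszm_", vals, fl)

    vals, fl = _gl_j_matrix_features(tm.gldzm, tm.n_voxels, _GLDZM_NAMES)
    add("gldzm_", vals, fl)

    vals, fl = ngtdm_features(tm.ngtdm_s, tm.ngtdm_n)
    add("ngtdm_", vals, fl)

    vals, fl = _gl_j_matrix_features(tm.ngldm, tm.n_voxels, _NGLDM_NAMES)
    add("ngldm_", vals, fl)

    return out, flags
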
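"""Naive, literal-formula reference implementations used as test oracles.

Everything here is written for clarity and independence from the
package's vectorized code paths: explicit Python loops over voxels,
pairs and matrix cells, directly transcribing the textbook definitions.
Shared conventions (documented with the package's feature definitions):
base-2 entropies, degenerate-case values, merged run/pair counts
normalized by voxels x directions.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

OFFSETS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
DIRECTIONS_13 = [d for d in OFFSETS_26 if next(x for x in d if x != 0) > 0]


def in_grid(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


# ------------------------------------------------------------- matrices


def oracle_glcm(levels, mask, G, direction=None):
    """Co-occurrence counts; merged over 13 directions unless one is given."""
    shape = levels.shape
    dirs = [direction, tuple(-x for x in direction)] if direction else OFFSETS_26
    M = np.zeros((G, G), dtype=np.int64)
    for v in product(*[range(s) for s in shape]):
        if not mask[v]:
            continue
        for d in dirs:
            u = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if in_grid(shape, u) and mask[u]:
                M[levels[v] - 1, levels[u] - 1] += 1
    return M


def oracle_glrlm(levels, mask, G, direction):
    """Run-length counts along one direction (maximal equal-level runs)."""
    shape = levels.shape
    runs = {}
    for v in product(*[range(s) for s in shape]):
        if not mask[v]:
            continue
        prev = (v[0] - direction[0], v[1] - direction[1], v[2] - direction[2])
        if in_grid(shape, prev) and mask[prev] and levels[prev] == levels[v]:
            continue  # not a run start
        g = levels[v]
        length = 1
        u = (v[0] + direction[0], v[1] + direction[1], v[2] + direction[2])
        while in_grid(shape, u) and mask[u] and levels[u] == g:
            length += 1
            u = (u[0] + direction[0], u[1] + direction[1], u[2] + direction[2])
        runs[(g, length)] = runs.get((g, length), 0) + 1
    rmax = max((r for _, r in runs), default=1)
    M = np.zeros((G, rmax), dtype=np.int64)
    for (g, r), c in runs.items():
        M[g - 1, r - 1] = c
    return M


def oracle_zones(levels, mask, G):
    """26-connected equal-level zones: (level, size, min taxicab border distance)."""
    shape = levels.shape
    # exact taxicab distance to outside-mask (grid border = outside)
    outside = [
        v
        for v in product(*[range(-1, s + 1) for s in shape])
        if not in_grid(shape, v) or not mask[v]
    ]
    dist = {}
    for v in product(*[range(s) for s in shape]):
        if mask[v]:
            dist[v] = min(
                abs(v[0] - u[0]) + abs(v[1] - u[1]) + abs(v[2] - u[2]) for u in outside
            )
    seen = set()
    zones = []
    for v in product(*[range(s) for s in shape]):
        if not mask[v] or v in seen:
            continue
        g = levels[v]
        stack, comp = [v], {v}
        seen.add(v)
        while stack:
            w = stack.pop()
            for d in OFFSETS_26:
                u = (w[0] + d[0], w[1] + d[1], w[2] + d[2])
                if in_grid(shape, u) and mask[u] and u not in seen and levels[u] == g:
                    seen.add(u)
                    comp.add(u)
                    stack.append(u)
        zones.append((g, len(comp), min(dist[u] for u in comp)))
    return zones


def oracle_ngtdm(levels, mask, G):
    """Per-level difference sums s_i and counts n_i over in-mask neighborhoods."""
    shape = levels.shape
    s = np.zeros(G)
    n = np.zeros(G, dtype=np.int64)
    for v in product(*[range(sz) for sz in shape]):
        if not mask[v]:
            continue
        nb = [
            levels[v[0] + d[0], v[1] + d[1], v[2] + d[2]]
            for d in OFFSETS_26
            if in_grid(shape, (v[0] + d[0], v[1] + d[1], v[2] + d[2]))
            and mask[v[0] + d[0], v[1] + d[1], v[2] + d[2]]
        ]
        if not nb:
            continue
        g = levels[v]
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(nb) / len(nb))
    return s, n


def oracle_ngldm(levels, mask, G):
    """Dependence counts (alpha=0, Chebyshev distance 1, centre included)."""
    shape = levels.shape
    entries = {}
    jmax = 1
    for v in product(*[range(sz) for sz in shape]):
        if not mask[v]:
            continue
        g = levels[v]
        j = 1
        for d in OFFSETS_26:
            u = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if in_grid(shape, u) and mask[u] and levels[u] == g:
                j += 1
        jmax = max(jmax, j)
        entries[(g, j)] = entries.get((g, j), 0) + 1
    M = np.zeros((G, jmax), dtype=np.int64)
    for (g, j), c in entries.items():
        M[g - 1, j - 1] = c
    return M


# ------------------------------------------------------------- features


def _ent(values):
    return -sum(p * math.log2(p) for p in values if p > 0)


def oracle_glcm_features(M, with_mcc=False):
    G = M.shape[0]
    total = M.sum()
    names = [
        "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
        "difference_average", "difference_variance", "difference_entropy",
        "sum_average", "sum_variance", "sum_entropy", "angular_second_moment",
        "contrast", "dissimilarity", "inverse_difference",
        "inverse_difference_normalised", "inverse_difference_moment",
        "inverse_difference_moment_normalised", "inverse_variance",
        "correlation", "autocorrelation", "cluster_tendency", "cluster_shade",
        "cluster_prominence", "information_correlation_1",
        "information_correlation_2",
    ]
    if total == 0:
        out = {k: 0.0 for k in names}
        if with_mcc:
            out["maximal_correlation_coefficient"] = 0.0
        return out
    p = M / total
    out = {}
    out["joint_maximum"] = p.max()
    mu = sum((i + 1) * p[i, j] for i in range(G) for j in range(G))
    out["joint_average"] = mu
    out["joint_variance"] = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(G) for j in range(G))
    out["joint_entropy"] = _ent(p.ravel())
    pd_ = [sum(p[i, j] for i in range(G) for j in range(G) if abs(i - j) == k) for k in range(G)]
    da = sum(k * pd_[k] for k in range(G))
    out["difference_average"] = da
    out["difference_variance"] = sum((k - da) ** 2 * pd_[k] for k in range(G))
    out["difference_entropy"] = _ent(pd_)
    ps = [sum(p[i, j] for i in range(G) for j in range(G) if i + j + 2 == k) for k in range(2, 2 * G + 1)]
    sa = sum((k + 2) * ps[k] for k in range(len(ps)))
    out["sum_average"] = sa
    out["sum_variance"] = sum((k + 2 - sa) ** 2 * ps[k] for k in range(len(ps)))
    out["sum_entropy"] = _ent(ps)
    out["angular_second_moment"] = sum(p[i, j] ** 2 for i in range(G) for j in range(G))
    out["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(G) for j in range(G))
    out["dissimilarity"] = sum(abs(i - j) * p[i, j] for i in range(G) for j in range(G))
    out["inverse_difference"] = sum(p[i, j] / (1 + abs(i - j)) for i in range(G) for j in range(G))
    out["inverse_difference_normalised"] = sum(
        p[i, j] / (1 + abs(i - j) / G) for i in range(G) for j in range(G)
    )
    out["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G)
    )
    out["inverse_difference_moment_normalised"] = sum(
        p[i, j] / (1 + (i - j) ** 2 / G**2) for i in range(G) for j in range(G)
    )
    out["inverse_variance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(G) for j in range(G) if i != j
    )
    px = [sum(p[i, j] for j in range(G)) for i in range(G)]
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(G))
    if var <= 0:
        out["correlation"] = 0.0
    else:
        out["correlation"] = sum(
            (i + 1 - mu) * (j + 1 - mu) * p[i, j] for i in range(G) for j in range(G)
        ) / var
    out["autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j] for i in range(G) for j in range(G))
    for power, key in ((2, "cluster_tendency"), (3, "cluster_shade"), (4, "cluster_prominence")):
        out[key] = sum(
            (i + 1 + j + 1 - 2 * mu) ** power * p[i, j] for i in range(G) for j in range(G)
        )
    hxy = out["joint_entropy"]
    hx = _ent(px)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * px[j])
        for i in range(G)
        for j in range(G)
        if p[i, j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j])
        for i in range(G)
        for j in range(G)
        if px[i] * px[j] > 0
    )
    out["information_correlation_1"] = 0.0 if hx <= 0 else (hxy - hxy1) / hx
    out["information_correlation_2"] = math.sqrt(max(0.0, 1.0 - 2.0 ** (-2 * (hxy2 - hxy))))
    if with_mcc:
        nz = [i for i in range(G) if px[i] > 0]
        if len(nz) <= 1:
            out["maximal_correlation_coefficient"] = 1.0
        else:
            Q = np.zeros((len(nz), len(nz)))
            for a, i in enumerate(nz):
                for b, j in enumerate(nz):
                    Q[a, b] = sum(
                        p[i, k] * p[j, k] / (px[i] * px[k]) for k in nz
                    )
            eig = sorted(np.real(np.linalg.eigvals(Q)))
            out["maximal_correlation_coefficient"] = math.sqrt(max(0.0, eig[-2]))
    return out


def oracle_gl_j_features(M, n_denom, names):
    """Template features of a grey-level x size-like matrix (literal sums)."""
    Ns = M.sum()
    if Ns == 0:
        return {k: 0.0 for k in names}
    G, J = M.shape
    vals = []
    vals.append(sum(M[g, j] / (j + 1) ** 2 for g in range(G) for j in range(J)) / Ns)
    vals.append(sum(M[g, j] * (j + 1) ** 2 for g in range(G) for j in range(J)) / Ns)
    vals.append(sum(M[g, j] / (g + 1) ** 2 for g in range(G) for j in range(J)) / Ns)
    vals.append(sum(M[g, j] * (g + 1) ** 2 for g in range(G) for j in range(J)) / Ns)
    vals.append(sum(M[g, j] / ((g + 1) ** 2 * (j + 1) ** 2) for g in range(G) for j in range(J)) / Ns)
    vals.append(sum(M[g, j] * (g + 1) ** 2 / (j + 1) ** 2 for g in range(G) for j in range(J)) / Ns)
    vals.append(sum(M[g, j] * (j + 1) ** 2 / (g + 1) ** 2 for g in range(G) for j in range(J)) / Ns)
    vals.append(sum(M[g, j] * (g + 1) ** 2 * (j + 1) ** 2 for g in range(G) for j in range(J)) / Ns)
    sg = [sum(M[g, j] for j in range(J)) for g in range(G)]
    sj = [sum(M[g, j] for g in range(G)) for j in range(J)]
    vals.append(sum(x**2 for x in sg) / Ns)
    vals.append(sum(x**2 for x in sg) / Ns**2)
    vals.append(sum(x**2 for x in sj) / Ns)
    vals.append(sum(x**2 for x in sj) / Ns**2)
    vals.append(Ns / n_denom)
    mu_g = sum((g + 1) * sg[g] for g in range(G)) / Ns
    vals.append(sum((g + 1) ** 2 * sg[g] for g in range(G)) / Ns - mu_g**2)
    mu_j = sum((j + 1) * sj[j] for j in range(J)) / Ns
    vals.append(sum((j + 1) ** 2 * sj[j] for j in range(J)) / Ns - mu_j**2)
    vals.append(_ent((M / Ns).ravel()))
    if len(names) == 17:
        vals.append(sum((M[g, j] / Ns) ** 2 for g in range(G) for j in range(J)))
    return dict(zip(names, vals))


def oracle_ngtdm_features(s, n):
    Nv = n.sum()
    out = {k: 0.0 for k in ("coarseness", "contrast", "busyness", "complexity", "strength")}
    if Nv == 0:
        return out
    G = len(n)
    p = n / Nv
    nz = [i for i in range(G) if p[i] > 0]
    denom = sum(p[i] * s[i] for i in range(G))
    out["coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if len(nz) > 1:
        Ngp = len(nz)
        out["contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in nz for j in nz)
            / (Ngp * (Ngp - 1))
            * sum(s)
            / Nv
        )
        denb = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in nz for j in nz)
        out["busyness"] = denom / denb if denb > 0 else 0.0
        out["complexity"] = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in nz
                for j in nz
            )
            / Nv
        )
        ssum = sum(s)
        out["strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in nz for j in nz) / ssum
            if ssum > 0
            else 0.0
        )
    return out


GLRLM_NAMES = (
    "short_runs_emphasis", "long_runs_emphasis", "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis", "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis", "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised", "run_length_non_uniformity",
    "run_length_non_uniformity_normalised", "run_percentage",
    "grey_level_variance", "run_length_variance", "run_entropy",
)
GLSZM_NAMES = (
    "small_zone_emphasis", "large_zone_emphasis", "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis", "small_zone_low_grey_level_emphasis",
    "small_zone_high_grey_level_emphasis", "large_zone_low_grey_level_emphasis",
    "large_zone_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised", "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalised", "zone_percentage",
    "grey_level_variance", "zone_size_variance", "zone_size_entropy",
)
GLDZM_NAMES = (
    "small_distance_emphasis", "large_distance_emphasis",
    "low_grey_level_zone_emphasis", "high_grey_level_zone_emphasis",
    "small_distance_low_grey_level_emphasis", "small_distance_high_grey_level_emphasis",
    "large_distance_low_grey_level_emphasis", "large_distance_high_grey_level_emphasis",
    "grey_level_non_uniformity", "grey_level_non_uniformity_normalised",
    "zone_distance_non_uniformity", "zone_distance_non_uniformity_normalised",
    "zone_percentage", "grey_level_variance", "zone_distance_variance",
    "zone_distance_entropy",
)
NGLDM_NAMES = (
    "low_dependence_emphasis", "high_dependence_emphasis",
    "low_grey_level_count_emphasis", "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis", "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis", "high_dependence_high_grey_level_emphasis",
    "grey_level_non_uniformity", "grey_level_non_uniformity_normalised",
    "dependence_count_non_uniformity", "dependence_count_non_uniformity_normalised",
    "dependence_count_percentage", "grey_level_variance",
    "dependence_count_variance", "dependence_count_entropy",
    "dependence_count_energy",
)


def oracle_all_texture_features(levels, mask, G):
    """All 137 texture features from scratch, naive implementations only."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    out = {}

    merged = oracle_glcm(levels, mask, G)
    for k, v in oracle_glcm_features(merged, with_mcc=True).items():
        out["glcm_" + k] = v
    per_dir = [oracle_glcm(levels, mask, G, direction=d) for d in DIRECTIONS_13]
    per_dir = [m for m in per_dir if m.sum() > 0]
    if per_dir:
        feats = [oracle_glcm_features(m) for m in per_dir]
        for k in feats[0]:
            out["glcm_avg_" + k] = sum(f[k] for f in feats) / len(feats)
    else:
        for k in oracle_glcm_features(np.zeros((G, G), dtype=np.int64)):
            out["glcm_avg_" + k] = 0.0

    rl = [oracle_glrlm(levels, mask, G, d) for d in DIRECTIONS_13]
    width = max(m.shape[1] for m in rl)
    merged_rl = np.zeros((G, width), dtype=np.int64)
    for m in rl:
        merged_rl[:, : m.shape[1]] += m
    for k, v in oracle_gl_j_features(merged_rl, n_vox * 13, GLRLM_NAMES).items():
        out["glrlm_" + k] = v
    rl_nonempty = [m for m in rl if m.sum() > 0]
    if rl_nonempty:
        feats = [oracle_gl_j_features(m, n_vox, GLRLM_NAMES) for m in rl_nonempty]
        for k in GLRLM_NAMES:
            out["glrlm_avg_" + k] = sum(f[k] for f in feats) / len(feats)
    else:
        for k in GLRLM_NAMES:
            out["glrlm_avg_" + k] = 0.0

    zones = oracle_zones(levels, mask, G)
    smax = max(s for _, s, _ in zones)
    dmax = max(d for _, _, d in zones)
    szm = np.zeros((G, smax), dtype=np.int64)
    dzm = np.zeros((G, dmax), dtype=np.int64)
    for g, s, d in zones:
        szm[g - 1, s - 1] += 1
        dzm[g - 1, d - 1] += 1
    for k, v in oracle_gl_j_features(szm, n_vox, GLSZM_NAMES).items():
        out["glszm_" + k] = v
    for k, v in oracle_gl_j_features(dzm, n_vox, GLDZM_NAMES).items():
        out["gldzm_" + k] = v

    s, n = oracle_ngtdm(levels, mask, G)
    for k, v in oracle_ngtdm_features(s, n).items():
        out["ngtdm_" + k] = v

    for k, v in oracle_gl_j_features(oracle_ngldm(levels, mask, G), n_vox, NGLDM_NAMES).items():
        out["ngldm_" + k] = v
    return out


# -------------------------------------------------- geometry and metrics


def oracle_rim(tumor, spacing, distance_mm, exclusions=()):
    """Peritumoral rim by exhaustive double loop over voxel centres."""
    tumor = np.asarray(tumor, dtype=bool)
    sp = np.asarray(spacing, dtype=float)
    t_coords = np.argwhere(tumor) * sp
    rim = np.zeros_like(tumor)
    for v in product(*[range(s) for s in tumor.shape]):
        if tumor[v]:
            continue
        c = np.array(v) * sp
        d2 = ((t_coords - c) ** 2).sum(axis=1)
        if d2.min() <= distance_mm**2 + 1e-12:
            rim[v] = True
    for exc in exclusions:
        rim &= ~np.asarray(exc, dtype=bool)
    return rim


def oracle_auc(scores, labels):
    """AUC by exhaustive pair counting with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def oracle_concordance(lp, times, events):
    """Harrell's C by exhaustive censoring-aware pair enumeration."""
    lp = np.asarray(lp, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    num = den = 0.0
    n = len(lp)
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] == t[j]:
                continue
            short, long_ = (i, j) if t[i] < t[j] else (j, i)
            if not e[short]:
                continue
            den += 1
            if lp[short] > lp[long_]:
                num += 1
            elif lp[short] == lp[long_]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den
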
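"""Synthetic phantoms and cohorts with known ground truth.

Patient MR data for recurrent glioblastoma cannot be shared, so every
downstream stage is exercised on synthetic inputs whose ground truth is
known analytically:

* :func:`generate_phantom` builds aligned pre-/post-contrast T1-like
  volumes containing an ellipsoidal contrast-enhancing tumor with a
  necrotic core, axis-aligned reference boxes for contralateral white
  matter and the vitreous body, and optionally a resection-cavity-like
  exclusion box.  Scanner variability is modelled as an affine
  intensity distortion (gain/offset) plus Gaussian noise.
* :func:`simulate_cohort` draws a radiomics-like feature table with a
  block-correlation structure (each block one latent factor, features =
  scaled latent + independent noise), a binary methylation-like label
  from a logistic model on the latent scores, and exponential
  proportional-hazards event times for the two survival endpoints with
  independent uniform censoring tuned to a target rate.

Cohort defaults mirror the clinical study the pipeline targets: 69
training and 49 validation patients (16 of the latter without a
methylation label), seven latent feature groups, and a single
informative group whose observed-feature discrimination is calibrated
to a theoretical AUC of 0.67.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .grids import VoiMask, VoxelGrid
from .io import ClinicalRecord
from .tables import FeatureTable

# -------------------------------------------------------------- phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue intensities and acquisition model of one phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_center_mm: tuple[float, float, float] = (32.0, 32.0, 32.0)
    tumor_semiaxes_mm: tuple[float, float, float] = (13.0, 11.0, 9.0)
    necrotic_core_fraction: float = 0.25
    rim_enhancement_contrast: float = 150.0
    wm_box_mm: tuple[tuple[float, float], ...] = ((4.0, 16.0), (4.0, 16.0), (4.0, 16.0))
    vitreous_box_mm: tuple[tuple[float, float], ...] = ((48.0, 60.0), (48.0, 60.0), (4.0, 14.0))
    exclusion_box_mm: tuple[tuple[float, float], ...] | None = None
    background_mean: float = 200.0
    wm_mean: float = 220.0
    vitreous_mean: float = 30.0
    necrotic_mean: float = 80.0
    noise_sd: float = 8.0
    scanner_gain: float = 1.0
    scanner_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.tumor_semiaxes_mm):
            raise ValueError("tumor semi-axes must be positive")
        if not 0.0 <= self.necrotic_core_fraction < 1.0:
            raise ValueError("necrotic core fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.scanner_gain == 0:
            raise ValueError("scanner gain must be nonzero")


def _box_mask(coords, box) -> np.ndarray:
    m = np.ones(coords[0].shape, dtype=bool)
    for axis in range(3):
        lo, hi = box[axis]
        m &= (coords[axis] >= lo) & (coords[axis] <= hi)
    return m


def generate_phantom(spec: PhantomSpec):
    """Build one phantom.

    Returns ``(pre_grid, post_grid, masks)`` with masks for roles
    ``tumoral``, ``wm_reference``, ``vitreous_reference`` and, when an
    exclusion box is configured, ``exclusion``.  The same spec and seed
    always produce bit-identical volumes.
    """
    sp = spec.spacing
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(spec.grid_shape, sp)], indexing="ij"
    )

    c = spec.tumor_center_mm
    a = spec.tumor_semiaxes_mm
    r2 = sum(((coords[i] - c[i]) / a[i]) ** 2 for i in range(3))
    tumor = r2 <= 1.0
    core_scale = spec.necrotic_core_fraction ** (1.0 / 3.0)
    core = r2 <= core_scale**2 if spec.necrotic_core_fraction > 0 else np.zeros_like(tumor)

    wm = _box_mask(coords, spec.wm_box_mm)
    vitreous = _box_mask(coords, spec.vitreous_box_mm)
    regions = {"tumoral": tumor, "wm_reference": wm, "vitreous_reference": vitreous}
    if spec.exclusion_box_mm is not None:
        regions["exclusion"] = _box_mask(coords, spec.exclusion_box_mm)

    names = list(regions)
    for i, n1 in enumerate(names):
        for n2 in names[i + 1 :]:
            if np.any(regions[n1] & regions[n2]):
                raise ValueError(f"phantom ROIs overlap: {n1!r} and {n2!r}")

    base = np.full(spec.grid_shape, spec.background_mean, dtype=np.float64)
    base[wm] = spec.wm_mean
    base[vitreous] = spec.vitreous_mean
    if "exclusion" in regions:
        base[regions["exclusion"]] = spec.vitreous_mean  # cavity: fluid-like

    pre = base.copy()
    pre[tumor] = spec.background_mean
    pre[core] = spec.necrotic_mean
    post = base.copy()
    post[tumor] = spec.background_mean + spec.rim_enhancement_contrast
    post[core] = spec.necrotic_mean

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        pre = pre + rng.normal(0.0, spec.noise_sd, size=pre.shape)
        post = post + rng.normal(0.0, spec.noise_sd, size=post.shape)
    pre = spec.scanner_gain * pre + spec.scanner_offset
    post = spec.scanner_gain * post + spec.scanner_offset

    masks = {
        role: VoiMask(vals, sp, role)
        for role, vals in regions.items()
        if role != "exclusion" or vals.any()
    }
    return (
        VoxelGrid(pre, sp),
        VoxelGrid(post, sp),
        masks,
    )


# ---------------------------------------------------------------- cohorts


def theoretical_feature_auc(beta: float, rho: float, intercept: float = 0.0, n_nodes: int = 96) -> float:
    """AUC of one observed block feature against the simulated label.

    The label is Bernoulli(sigmoid(intercept + beta*z)) on the latent
    score z ~ N(0,1); the feature is sqrt(rho)*z + sqrt(1-rho)*noise.
    Evaluated by Gauss-Hermite quadrature.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / np.sqrt(2 * np.pi)
    pz = special.expit(intercept + beta * nodes)
    w1 = w * pz
    w0 = w * (1 - pz)
    if rho >= 1.0:
        gt = (nodes[:, None] > nodes[None, :]).astype(float)
    else:
        gt = stats.norm.cdf(
            np.sqrt(rho) * (nodes[:, None] - nodes[None, :]) / np.sqrt(2 * (1 - rho))
        )
    num = float((w1[:, None] * w0[None, :] * gt).sum())
    return num / (w1.sum() * w0.sum())


def logistic_effect_for_auc(target_auc: float, rho: float, intercept: float = 0.0) -> float:
    """Latent-scale logistic coefficient giving a target feature AUC."""
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target AUC must be in (0.5, 1)")
    return float(
        optimize.brentq(
            lambda b: theoretical_feature_auc(b, rho, intercept) - target_auc, 1e-6, 50.0
        )
    )


@dataclass(frozen=True)
class CohortSpec:
    """Size, correlation structure and planted effects of one cohort."""

    n: int = 118  # 69 training + 49 validation
    n_validation: int = 49
    n_groups: int = 7
    features_per_group: int = 10
    within_correlation: float = 0.8
    logistic_effects: tuple[float, ...] | None = None  # per latent group
    logistic_intercept: float = -0.37  # ~41% methylated prevalence
    pfs2_log_hazards: tuple[float, ...] | None = None
    os_log_hazards: tuple[float, ...] | None = None
    pfs2_baseline_rate: float = 0.2567  # per month; median ~2.7 months
    os_baseline_rate: float = 0.0613  # per month; median ~11.3 months
    censoring_rate: float = 0.10
    n_mgmt_missing_validation: int = 16
    target_feature_auc: float = 0.67  # calibration of the default MGMT effect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("cohort size must be at least 10")
        if not 0.0 <= self.within_correlation < 1.0:
            raise ValueError("within-group correlation must be in [0, 1)")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring target must be in [0, 1)")
        if not 0 <= self.n_validation < self.n:
            raise ValueError("n_validation must be in [0, n)")
        g = self.n_groups
        if self.logistic_effects is None:
            beta = logistic_effect_for_auc(
                self.target_feature_auc, self.within_correlation, self.logistic_intercept
            )
            object.__setattr__(self, "logistic_effects", (beta,) + (0.0,) * (g - 1))
        if self.pfs2_log_hazards is None:
            object.__setattr__(self, "pfs2_log_hazards", (0.4,) + (0.0,) * (g - 1))
        if self.os_log_hazards is None:
            object.__setattr__(self, "os_log_hazards", (0.35,) + (0.0,) * (g - 1))
        for name in ("logistic_effects", "pfs2_log_hazards", "os_log_hazards"):
            vec = getattr(self, name)
            if len(vec) != g:
                raise ValueError(
                    f"{name} has length {len(vec)} but there are {g} latent groups"
                )


@dataclass(frozen=True)
class SimulatedCohort:
    """Feature table, clinical records and the generating ground truth."""

    features: FeatureTable
    clinical: list[ClinicalRecord]
    truth: dict


def _censor(rng: np.random.Generator, times: np.ndarray, target: float):
    """Independent uniform censoring tuned to the target censored fraction."""
    if target <= 0:
        return times.copy(), np.ones(len(times), dtype=bool), np.inf
    # P(censored) = E[min(T/Tmax, 1)] is decreasing in Tmax; solve for Tmax
    def frac(tmax):
        return float(np.minimum(times / tmax, 1.0).mean()) - target

    lo, hi = times.min() * 1e-6 + 1e-9, times.max() / max(target, 1e-9) * 10 + 1.0
    tmax = float(optimize.brentq(frac, lo, hi))
    c = rng.uniform(0.0, tmax, size=len(times))
    observed = np.minimum(times, c)
    event = times <= c
    return observed, event, tmax


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw one cohort under the spec's generative model."""
    rng = np.random.default_rng(spec.seed)
    n, g, f = spec.n, spec.n_groups, spec.features_per_group
    rho = spec.within_correlation

    z = rng.standard_normal((n, g))  # latent group scores
    eps = rng.standard_normal((n, g, f))
    x = np.sqrt(rho) * z[:, :, None] + np.sqrt(1.0 - rho) * eps
    x = x.reshape(n, g * f)

    lin = spec.logistic_intercept + z @ np.asarray(spec.logistic_effects)
    y = rng.uniform(size=n) < special.expit(lin)

    def draw_times(log_hazards, baseline):
        hz = baseline * np.exp(z @ np.asarray(log_hazards))
        return rng.exponential(1.0 / hz)

    t_pfs2 = draw_times(spec.pfs2_log_hazards, spec.pfs2_baseline_rate)
    t_os = draw_times(spec.os_log_hazards, spec.os_baseline_rate)
    pfs2_obs, pfs2_event, tmax_pfs2 = _censor(rng, t_pfs2, spec.censoring_rate)
    os_obs, os_event, tmax_os = _censor(rng, t_os, spec.censoring_rate)

    n_train = n - spec.n_validation
    ids = [f"P{i:04d}" for i in range(n)]
    cohorts = ["training"] * n_train + ["validation"] * spec.n_validation
    # methylation label unavailable for some validation patients
    missing = set()
    if spec.n_mgmt_missing_validation > 0 and spec.n_validation > 0:
        k = min(spec.n_mgmt_missing_validation, spec.n_validation)
        missing = set(
            rng.choice(np.arange(n_train, n), size=k, replace=False).tolist()
        )

    records = [
        ClinicalRecord(
            patient_id=ids[i],
            mgmt="missing" if i in missing else ("methylated" if y[i] else "unmethylated"),
            pfs2_months=float(pfs2_obs[i]),
            pfs2_event=bool(pfs2_event[i]),
            os_months=float(os_obs[i]),
            os_event=bool(os_event[i]),
            cohort=cohorts[i],
        )
        for i in range(n)
    ]

    cols = [f"g{gi + 1}_f{fi + 1}" for gi in range(g) for fi in range(f)]
    table = FeatureTable(
        pd.DataFrame(x, index=pd.Index(ids, name="patient_id"), columns=cols),
        voi="simulated",
        provenance={"generator": "simulate_cohort", "seed": spec.seed},
    )
    truth = {
        "latent_scores": z,
        "group_of_feature": {c: c.split("_")[0] for c in cols},
        "logistic_effects": tuple(spec.logistic_effects),
        "logistic_intercept": spec.logistic_intercept,
        "pfs2_log_hazards": tuple(spec.pfs2_log_hazards),
        "os_log_hazards": tuple(spec.os_log_hazards),
        "within_correlation": rho,
        "censoring_tmax": {"pfs2": tmax_pfs2, "os": tmax_os},
        "theoretical_feature_auc": theoretical_feature_auc(
            spec.logistic_effects[0], rho, spec.logistic_intercept
        )
        if spec.logistic_effects[0] != 0
        else 0.5,
    }
    return SimulatedCohort(table, records, truth)
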
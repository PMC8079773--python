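"""End-to-end orchestration: data to feature tables to validated models.

One run walks the full workflow: acquire a cohort (synthetic phantoms +
simulated endpoints, or real volumes/masks/clinical table), construct
the tumoral and peritumoral VOIs, extract 180 features per VOI under
both intensity normalizations, audit image quality, and — per endpoint,
per normalization, per VOI — reduce the feature space, fit the
multivariable model on the training cohort and evaluate it on the
held-out validation cohort.  Every branch is attempted independently: a
branch may end with a model, with a recorded "no significant features"
outcome, or with a recorded error, without aborting its siblings.

All randomness funnels through a single seed, expanded deterministically
per stage, so a rerun of the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .endpoints import BinaryEndpoint, endpoints_from_clinical
from .features import extract_voi
from .geometry import below_volume_threshold, make_peritumoral_rim
from .io import read_clinical, read_mask, read_volume
from .models import (
    FittedModel,
    cross_validate_5fold,
    evaluate_binary,
    evaluate_survival,
    fit_multivariable,
    predict,
    stratify_logrank,
)
from .preprocess import NormalizationSpec
from .quality import compare_cohorts, compute_quality, metrics_table
from .selection import group_features, scale_features, screen_univariable
from .synthetic import CohortSpec, PhantomSpec, generate_phantom, simulate_cohort
from .tables import FeatureTable

ENDPOINTS = ("mgmt", "pfs2", "os")
VOIS = ("tumoral", "peritumoral")


def derive_seed(base: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{base}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class SyntheticInputs:
    n_patients: int = 24
    n_validation: int = 8
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    base_semiaxes_mm: tuple[float, float, float] = (10.0, 9.0, 8.0)
    semiaxis_jitter_mm: float = 2.0
    noise_sd: float = 8.0


@dataclass(frozen=True)
class RealInputs:
    volumes: dict[str, str] = field(default_factory=dict)  # patient -> NIfTI path
    tumor_masks: dict[str, str] = field(default_factory=dict)
    wm_masks: dict[str, str] = field(default_factory=dict)
    vitreous_masks: dict[str, str] = field(default_factory=dict)
    exclusion_masks: dict[str, str] = field(default_factory=dict)
    clinical_table: str = ""


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    output_dir: str = "runs/run"
    rim_distance_mm: float = 15.0
    horn_n_sim: int = 1000
    horn_percentile: float = 95.0
    endpoints: tuple[str, ...] = ENDPOINTS
    n_bins: int = 32
    bin_size: float = 50.0
    anchor_wm: float = 300.0
    anchor_vitreous: float = 0.0
    synthetic: SyntheticInputs | None = None
    real: RealInputs | None = None
    run_cv: bool = True

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.real is None):
            raise ValueError("exactly one of synthetic/real inputs must be configured")
        unknown = set(self.endpoints) - set(ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown endpoints {sorted(unknown)}")

    def normalizations(self) -> dict[str, NormalizationSpec]:
        return {
            "fixed_bin_number": NormalizationSpec(
                "fixed_bin_number", n_bins=self.n_bins, bin_size=self.bin_size,
                anchor_wm=self.anchor_wm, anchor_vitreous=self.anchor_vitreous,
            ),
            "linear_two_point": NormalizationSpec(
                "linear_two_point", n_bins=self.n_bins, bin_size=self.bin_size,
                anchor_wm=self.anchor_wm, anchor_vitreous=self.anchor_vitreous,
            ),
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic"):
            syn = dict(d["synthetic"])
            for key in ("grid_shape", "base_semiaxes_mm"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            d["synthetic"] = SyntheticInputs(**syn)
        else:
            d["synthetic"] = None
        d["real"] = RealInputs(**d["real"]) if d.get("real") else None
        if "endpoints" in d:
            d["endpoints"] = tuple(d["endpoints"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ------------------------------------------------------------ acquisition


def _synthetic_patients(cfg: RunConfig):
    """Phantoms + simulated clinical endpoints for a synthetic run."""
    syn = cfg.synthetic
    cohort = simulate_cohort(
        CohortSpec(
            n=syn.n_patients,
            n_validation=syn.n_validation,
            n_mgmt_missing_validation=0,
            seed=derive_seed(cfg.seed, "cohort"),
        )
    )
    rng = np.random.default_rng(derive_seed(cfg.seed, "phantom-jitter"))
    shape = syn.grid_shape
    center = tuple(s / 2.0 for s in shape)
    patients = {}
    for i, rec in enumerate(cohort.clinical):
        semi = tuple(
            float(np.clip(a + rng.uniform(-syn.semiaxis_jitter_mm, syn.semiaxis_jitter_mm), 3.0, min(shape) / 4))
            for a in syn.base_semiaxes_mm
        )
        spec = PhantomSpec(
            grid_shape=shape,
            tumor_center_mm=center,
            tumor_semiaxes_mm=semi,
            noise_sd=syn.noise_sd,
            scanner_gain=float(rng.uniform(0.8, 1.2)),
            scanner_offset=float(rng.uniform(-20, 20)),
            wm_box_mm=((3.0, 12.0),) * 3,
            vitreous_box_mm=(
                (shape[0] - 13.0, shape[0] - 4.0),
                (shape[1] - 13.0, shape[1] - 4.0),
                (3.0, 12.0),
            ),
            seed=derive_seed(cfg.seed, f"phantom-{i}"),
        )
        pre, post, masks = generate_phantom(spec)
        metadata = {
            "repetition_time": float(rng.uniform(400, 700)),
            "echo_time": float(rng.uniform(8, 20)),
        }
        patients[rec.patient_id] = {
            "pre": pre,
            "post": post,
            "masks": masks,
            "metadata": metadata,
            "clinical": rec,
        }
    return patients, cohort.clinical


def _real_patients(cfg: RunConfig):
    real = cfg.real
    clinical = read_clinical(real.clinical_table)
    by_id = {r.patient_id: r for r in clinical}
    patients = {}
    for pid, vol_path in real.volumes.items():
        post = read_volume(vol_path)
        masks = {"tumoral": read_mask(real.tumor_masks[pid], post, "tumoral")}
        if pid in real.wm_masks:
            masks["wm_reference"] = read_mask(real.wm_masks[pid], post, "wm_reference")
        if pid in real.vitreous_masks:
            masks["vitreous_reference"] = read_mask(real.vitreous_masks[pid], post, "vitreous_reference")
        if pid in real.exclusion_masks:
            masks["exclusion"] = read_mask(real.exclusion_masks[pid], post, "exclusion")
        patients[pid] = {
            "pre": None,
            "post": post,
            "masks": masks,
            "metadata": {},
            "clinical": by_id[pid],
        }
    return patients, [by_id[p] for p in patients]


# --------------------------------------------------------------- branches


def train_branch(
    X_train: pd.DataFrame,
    endpoint,
    horn_n_sim: int = 1000,
    horn_percentile: float = 95.0,
    seed: int = 0,
):
    """Scale, group, screen and fit on training data alone.

    Returns ``(model_or_None, details)``; no statistic of any validation
    cohort enters this function.
    """
    details: dict = {}
    if isinstance(endpoint, BinaryEndpoint):
        ids = [i for i in X_train.index if i in endpoint.labels.index]
        X_train = X_train.loc[ids]
        endpoint = endpoint.subset(ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled, _, scaling = scale_features(X_train)
    details["dropped_constant"] = list(scaling.dropped_constant)
    try:
        grouping = group_features(
            scaled, n_sim=horn_n_sim, percentile=horn_percentile, seed=seed
        )
    except ValueError:
        # no components retained: single-group fallback
        from .selection import PCGrouping

        grouping = PCGrouping(
            1,
            pd.DataFrame(index=scaled.columns, data={"pc1": 1.0}),
            {f: 0 for f in scaled.columns},
            {0: scaled.shape[1]},
        )
        details["horn_fallback_single_group"] = True
    details["n_groups"] = grouping.k
    details["group_sizes"] = dict(sorted(grouping.group_sizes.items()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screening = screen_univariable(scaled, grouping, endpoint)
    details["candidates"] = screening.candidates
    if not screening.candidates:
        return None, details
    sc = {f: {"mean": scaling.means[f], "std": scaling.stds[f]} for f in screening.candidates}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_multivariable(scaled, endpoint, screening.candidates, scaling=sc)
    return model, details


def _evaluate_branch(model: FittedModel, X, endpoint, cohort_tag: str):
    scores = predict(model, X)
    if isinstance(endpoint, BinaryEndpoint):
        ids = [i for i in scores.index if i in endpoint.labels.index]
        rep = evaluate_binary(scores.loc[ids], endpoint.labels.loc[ids])
    else:
        rep = evaluate_survival(scores, endpoint.times.loc[scores.index], endpoint.events.loc[scores.index])
    return {
        "cohort": cohort_tag,
        "metric_name": rep.metric_name,
        "metric": rep.metric,
        "ci_low": rep.ci_low,
        "ci_high": rep.ci_high,
        "n": rep.n,
    }


def run_end_to_end(config: RunConfig) -> dict:
    """Execute every branch of the workflow and write a run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        patients, clinical = _synthetic_patients(config)
    else:
        patients, clinical = _real_patients(config)

    # ---- VOI construction and minimum-volume audit
    excluded = []
    for pid, p in list(patients.items()):
        tumor = p["masks"]["tumoral"]
        if below_volume_threshold(tumor):
            excluded.append({"patient_id": pid, "reason": "tumor volume < 0.2 ml"})
            del patients[pid]
            continue
        exclusions = [p["masks"]["exclusion"]] if "exclusion" in p["masks"] else []
        p["masks"]["peritumoral"] = make_peritumoral_rim(
            tumor, exclusions, distance_mm=config.rim_distance_mm
        )
    clinical = [r for r in clinical if r.patient_id in patients]

    # ---- feature extraction, per normalization x VOI
    norms = config.normalizations()
    tables: dict[tuple[str, str], FeatureTable] = {}
    for norm_name, spec in norms.items():
        for voi in VOIS:
            rows = {}
            for pid, p in patients.items():
                fv = extract_voi(
                    p["post"],
                    p["masks"][voi],
                    spec,
                    wm_mask=p["masks"].get("wm_reference"),
                    vitreous_mask=p["masks"].get("vitreous_reference"),
                )
                rows[pid] = fv.values
            df = pd.DataFrame.from_dict(rows, orient="index")
            df.index.name = "patient_id"
            table = FeatureTable(df, voi=voi, provenance={"normalization": norm_name})
            table.write_csv(out / f"features_{norm_name}_{voi}.csv")
            tables[(norm_name, voi)] = table

    # ---- image quality audit
    qmetrics = [
        compute_quality(p["post"], p["metadata"], scan_id=pid, cohort=p["clinical"].cohort)
        for pid, p in patients.items()
    ]
    metrics_table(qmetrics).to_csv(out / "quality_metrics.csv")
    qa = [m for m in qmetrics if m.cohort == "training"]
    qb = [m for m in qmetrics if m.cohort == "validation"]
    quality_report = None
    if len(qa) >= 3 and len(qb) >= 3:
        location = compare_cohorts(qa, qb, dispersion=False)
        spread = compare_cohorts(qa, qb, dispersion=True)
        location["mode"] = "location"
        spread["mode"] = "dispersion"
        quality_report = pd.concat([location, spread])
        quality_report.to_csv(out / "quality_comparison.csv")

    # ---- modelling branches
    eps = endpoints_from_clinical(clinical)
    train_ids = [r.patient_id for r in clinical if r.cohort == "training"]
    val_ids = [r.patient_id for r in clinical if r.cohort == "validation"]
    branches = []
    for endpoint_name in config.endpoints:
        endpoint = eps[endpoint_name]
        for norm_name in norms:
            for voi in VOIS:
                branch = {
                    "endpoint": endpoint_name,
                    "normalization": norm_name,
                    "voi": voi,
                    "status": None,
                }
                try:
                    table = tables[(norm_name, voi)]
                    X_train = table.data.loc[[i for i in train_ids if i in table.data.index]]
                    X_val = table.data.loc[[i for i in val_ids if i in table.data.index]]
                    ep_train = endpoint.subset([i for i in X_train.index]) if not isinstance(endpoint, BinaryEndpoint) else endpoint
                    model, details = train_branch(
                        X_train,
                        ep_train,
                        horn_n_sim=config.horn_n_sim,
                        horn_percentile=config.horn_percentile,
                        seed=derive_seed(config.seed, f"horn-{endpoint_name}-{norm_name}-{voi}"),
                    )
                    branch["details"] = details
                    if model is None or model.is_empty:
                        branch["status"] = "no_model"
                        branches.append(branch)
                        continue
                    stem = f"model_{endpoint_name}_{norm_name}_{voi}"
                    model.to_json(out / f"{stem}.json")
                    evaluations = [_evaluate_branch(model, X_train, endpoint, "training")]
                    if len(X_val):
                        try:
                            evaluations.append(_evaluate_branch(model, X_val, endpoint, "validation"))
                        except ValueError as err:
                            branch["validation_error"] = str(err)
                    branch["evaluations"] = evaluations
                    if endpoint_name in ("pfs2", "os") and len(X_val):
                        strat = stratify_logrank(
                            predict(model, X_train).to_numpy(),
                            predict(model, X_val).to_numpy(),
                            endpoint.times.loc[X_val.index].to_numpy(),
                            endpoint.events.loc[X_val.index].to_numpy(),
                        )
                        branch["stratification"] = strat
                    if config.run_cv and len(X_train) >= 10:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            cv = cross_validate_5fold(
                                X_train,
                                ep_train,
                                lambda Xf, epf: train_branch(
                                    Xf,
                                    epf,
                                    horn_n_sim=max(100, config.horn_n_sim // 10),
                                    horn_percentile=config.horn_percentile,
                                    seed=derive_seed(config.seed, f"cv-{endpoint_name}-{norm_name}-{voi}"),
                                )[0],
                                seed=derive_seed(config.seed, f"folds-{endpoint_name}-{norm_name}-{voi}"),
                            )
                        branch["cross_validation"] = cv
                    branch["status"] = "model"
                    branch["model_features"] = list(model.features)
                except Exception as err:  # a branch failure never kills siblings
                    branch["status"] = "error"
                    branch["error"] = f"{type(err).__name__}: {err}"
                branches.append(branch)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_patients": len(patients),
        "excluded": excluded,
        "branches": branches,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    eval_rows = []
    for b in branches:
        for ev in b.get("evaluations", []):
            eval_rows.append(
                {"endpoint": b["endpoint"], "normalization": b["normalization"], "voi": b["voi"], **ev}
            )
    if eval_rows:
        pd.DataFrame(eval_rows).to_csv(out / "evaluations.csv", index=False)
    return manifest
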
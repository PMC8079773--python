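"""Multivariable outcome models and their evaluation.

Logistic regression serves the binary methylation endpoint, Cox
proportional hazards the survival endpoints.  Model building starts
from all screened candidates and removes variables backward by the
Akaike information criterion until no removal lowers the AIC; the empty
(intercept-only / null) model takes part in the comparison, so a branch
can legitimately end with no model.

Evaluation: AUC by the Mann-Whitney statistic with a DeLong 95%
confidence interval for binary scores; Harrell's concordance index with
an asymptotic-normal interval for survival.  Risk stratification splits
at the median training prediction and compares the two groups by
log-rank test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy import stats


class ModelFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FittedModel:
    """A fitted logistic or Cox model with everything needed to apply it."""

    model_type: str  # "logistic" | "cox"
    features: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float  # 0.0 for cox
    aic: float
    scaling: dict[str, dict[str, float]] = field(default_factory=dict)  # feature -> mean/std
    flags: tuple[str, ...] = ()

    @property
    def is_empty(self) -> bool:
        return len(self.features) == 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_type": self.model_type,
            "features": list(self.features),
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "aic": self.aic,
            "scaling": self.scaling,
            "flags": list(self.flags),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            model_type=d["model_type"],
            features=tuple(d["features"]),
            coefficients=d["coefficients"],
            intercept=d["intercept"],
            aic=d["aic"],
            scaling=d.get("scaling", {}),
            flags=tuple(d.get("flags", ())),
        )


@dataclass(frozen=True)
class EvaluationReport:
    """Discrimination of one model on one cohort."""

    metric: float  # AUC or concordance index
    ci_low: float
    ci_high: float
    metric_name: str  # "auc" | "concordance"
    cohort: str = ""
    n: int = 0
    logrank_p: float | None = None
    risk_groups: dict | None = None


# ------------------------------------------------------------- fitting


def _null_cox_aic(times: np.ndarray, events: np.ndarray) -> float:
    """AIC of the null Cox model (Breslow partial likelihood, no covariates)."""
    order = np.argsort(times, kind="stable")
    t, e = np.asarray(times)[order], np.asarray(events)[order]
    n = len(t)
    ll = 0.0
    for i in range(n):
        if e[i]:
            at_risk = np.sum(t >= t[i])
            ll -= np.log(at_risk)
    return -2.0 * ll


def _fit_logistic(X: pd.DataFrame, y: np.ndarray, features: list[str]):
    design = sm.add_constant(X[features], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    return res


def _fit_cox(X: pd.DataFrame, times, events, features: list[str]):
    df = X[features].copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter(penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_time", event_col="_event")
    return cph


def _model_aic(X, endpoint_kind, y_or_te, features: list[str]) -> tuple[float, object]:
    if not features:
        if endpoint_kind == "logistic":
            y = y_or_te
            res = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
            return float(res.aic), res
        times, events = y_or_te
        return _null_cox_aic(times, events), None
    if endpoint_kind == "logistic":
        res = _fit_logistic(X, y_or_te, features)
        return float(res.aic), res
    times, events = y_or_te
    cph = _fit_cox(X, times, events, features)
    return float(cph.AIC_partial_), cph


def fit_multivariable(
    X: pd.DataFrame,
    endpoint,
    candidates: list[str],
    scaling: dict | None = None,
) -> FittedModel:
    """AIC-backward multivariable model over the screened candidates.

    ``endpoint`` is a :class:`~gliorad.endpoints.BinaryEndpoint` (logistic
    fit) or :class:`~gliorad.endpoints.SurvivalEndpoint` (Cox fit) aligned
    to ``X``'s index.  Starting from the full candidate model, the
    variable whose removal lowers the AIC the most is dropped, repeatedly,
    until no removal lowers it; the empty model participates, so the
    result may be empty (flagged ``no_model``).
    """
    from .endpoints import BinaryEndpoint

    if not candidates:
        raise ModelFitError("no candidate features supplied")
    missing = [c for c in candidates if c not in X.columns]
    if missing:
        raise ModelFitError(f"candidate features missing from the table: {missing}")

    if isinstance(endpoint, BinaryEndpoint):
        kind = "logistic"
        y = endpoint.labels.loc[X.index].to_numpy(dtype=float)
        y_or_te = y
    else:
        kind = "cox"
        times = endpoint.times.loc[X.index].to_numpy(dtype=float)
        events = endpoint.events.loc[X.index].to_numpy(dtype=bool)
        if events.sum() < 10:
            warnings.warn(
                f"only {int(events.sum())} events for the Cox fit; estimates may be unstable",
                stacklevel=2,
            )
        y_or_te = (times, events)

    current = list(candidates)
    # an unfittable variable set (separation, collinearity) is treated as
    # infinitely bad, so backward selection explores its subsets instead of
    # aborting; only a globally unfittable problem is an error
    try:
        current_aic, current_fit = _model_aic(X, kind, y_or_te, current)
    except Exception:
        current_aic, current_fit = np.inf, None

    while current:
        best_drop, best_aic, best_fit = None, None, None
        for var in current:
            reduced = [v for v in current if v != var]
            try:
                aic, fit = _model_aic(X, kind, y_or_te, reduced)
            except Exception:
                continue
            if best_aic is None or aic < best_aic:
                best_drop, best_aic, best_fit = var, aic, fit
        if best_aic is None or best_aic >= current_aic:
            break
        current.remove(best_drop)
        current_aic, current_fit = best_aic, best_fit

    flags = () if current else ("no_model",)
    if not current:
        return FittedModel(kind, (), {}, 0.0, current_aic, scaling or {}, flags)
    if current_fit is None or not np.isfinite(current_aic):
        raise ModelFitError(
            f"multivariable {kind} fit failed to converge for variables {current}"
        )
    if kind == "logistic":
        params = current_fit.params
        coefs = {v: float(params[v]) for v in current}
        intercept = float(params["const"])
    else:
        coefs = {v: float(current_fit.params_[v]) for v in current}
        intercept = 0.0
    return FittedModel(kind, tuple(current), coefs, intercept, current_aic, scaling or {}, flags)


def predict(model: FittedModel, features: pd.DataFrame) -> pd.Series:
    """Risk score per subject: probability (logistic) or log relative hazard (cox)."""
    if model.is_empty:
        raise ModelFitError("cannot predict from an empty model")
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise ModelFitError(f"features required by the model are missing: {missing}")
    X = features[list(model.features)].astype(float)
    if model.scaling:
        for f in model.features:
            sc = model.scaling.get(f)
            if sc:
                X[f] = (X[f] - sc["mean"]) / sc["std"]
    lp = X.to_numpy() @ np.array([model.coefficients[f] for f in model.features])
    lp = lp + model.intercept
    if model.model_type == "logistic":
        return pd.Series(1.0 / (1.0 + np.exp(-lp)), index=features.index)
    return pd.Series(lp, index=features.index)


# ----------------------------------------------------------- evaluation


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic, ties getting 1/2 credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute an AUC")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def evaluate_binary(scores, labels, alpha: float = 0.05) -> EvaluationReport:
    """AUC with a DeLong 95% confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    auc = auc_mann_whitney(scores, labels)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    v10 = (all_r[:m] - pos_r) / n  # structural components
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return EvaluationReport(
        metric=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        metric_name="auc",
        n=m + n,
    )


def harrell_concordance(linear_predictors, times, events):
    """Harrell's C over censoring-aware comparable pairs.

    A pair is comparable when the subject with the strictly shorter
    observed time had an event; a higher linear predictor for the
    shorter survivor counts as concordant, predictor ties as 1/2.
    Returns ``(C, per-subject influence array)``.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    n = len(lp)
    num = np.zeros(n)
    den = np.zeros(n)
    for i in range(n):
        if not e[i]:
            continue
        later = t > t[i]  # i is the (event) subject with shorter time
        if not later.any():
            continue
        score = np.where(lp[later] < lp[i], 1.0, np.where(lp[later] == lp[i], 0.5, 0.0))
        num[i] += score.sum()
        den[i] += later.sum()
        num[later] += score
        den[later] += 1
    total_pairs = den.sum() / 2.0
    if total_pairs == 0:
        raise ValueError("no comparable pairs: concordance is undefined")
    c = num.sum() / den.sum()
    with np.errstate(invalid="ignore"):
        infl = np.where(den > 0, num / den, c)
    return float(c), infl


def evaluate_survival(linear_predictors, times, events, alpha: float = 0.05) -> EvaluationReport:
    """Harrell's concordance with an asymptotic-normal 95% interval."""
    c, infl = harrell_concordance(linear_predictors, times, events)
    n = len(infl)
    var = 4.0 * np.var(infl, ddof=1) / n if n > 1 else 0.0
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return EvaluationReport(
        metric=c,
        ci_low=float(max(0.0, c - half)),
        ci_high=float(min(1.0, c + half)),
        metric_name="concordance",
        n=n,
    )


def stratify_logrank(train_scores, scores, times, events) -> dict:
    """Median-threshold risk stratification with a two-group log-rank test.

    The threshold is the median prediction in the training cohort;
    subjects scoring strictly above it form the high-risk group.
    """
    train_scores = np.asarray(train_scores, dtype=float)
    if train_scores.size == 0:
        raise ValueError("training scores are required to set the threshold")
    threshold = float(np.median(train_scores))
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    high = scores > threshold
    out = {
        "threshold": threshold,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "statistic": None,
        "p": None,
        "flag": None,
    }
    if high.all() or not high.any():
        out["flag"] = "empty_risk_group"
        return out
    res = logrank_test(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])
    out["statistic"] = float(res.test_statistic)
    out["p"] = float(res.p_value)
    return out


def cross_validate_5fold(features: pd.DataFrame, endpoint, train_branch, seed: int = 0, n_splits: int = 5):
    """Internal stratified 5-fold cross-validation of a full training branch.

    ``train_branch(X_train, endpoint_train)`` must re-run scaling,
    grouping, screening and fitting on the training fold alone and
    return a :class:`FittedModel` (or an empty one).  Folds are
    stratified by label (binary) or event flag (survival); a fold whose
    test part lacks a class or any event is skipped with a warning.
    """
    from sklearn.model_selection import StratifiedKFold

    from .endpoints import BinaryEndpoint

    is_binary = isinstance(endpoint, BinaryEndpoint)
    if is_binary:
        ids = [i for i in features.index if i in endpoint.labels.index]
    else:
        ids = list(features.index)
    X = features.loc[ids]
    strat = (
        endpoint.labels.loc[ids].to_numpy().astype(int)
        if is_binary
        else endpoint.events.loc[ids].to_numpy().astype(int)
    )
    if len(ids) < 10:
        raise ValueError("need at least 10 subjects for 5-fold cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_metrics, fold_details = [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(ids)), strat)):
        tr_ids = [ids[i] for i in tr]
        te_ids = [ids[i] for i in te]
        model = train_branch(X.loc[tr_ids], endpoint.subset(tr_ids))
        detail = {"fold": fold, "n_test": len(te_ids), "status": "ok", "metric": None}
        if model is None or model.is_empty:
            detail["status"] = "no_model"
            fold_details.append(detail)
            continue
        scores = predict(model, X.loc[te_ids])
        try:
            if is_binary:
                rep = evaluate_binary(scores, endpoint.labels.loc[te_ids])
            else:
                rep = evaluate_survival(
                    scores, endpoint.times.loc[te_ids], endpoint.events.loc[te_ids]
                )
        except ValueError as err:
            warnings.warn(f"fold {fold} skipped: {err}", stacklevel=2)
            detail["status"] = "skipped"
            fold_details.append(detail)
            continue
        detail["metric"] = rep.metric
        fold_metrics.append(rep.metric)
        fold_details.append(detail)
    return {
        "folds": fold_details,
        "mean_metric": float(np.mean(fold_metrics)) if fold_metrics else None,
        "n_evaluated_folds": len(fold_metrics),
    }
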
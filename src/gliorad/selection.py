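"""Feature-space reduction: scaling, PCA grouping, univariable screening.

The reduction follows a fixed recipe: (1) features are standardized on
the training cohort (the same transform is later applied to validation
data); (2) a principal component analysis of the training correlation
matrix is reduced to the components retained by Horn's parallel
analysis; (3) every feature is assigned to the retained component on
which its squared loading is largest, so each retained component
defines one group of correlated features; (4) within each group, the
feature with the best univariable discrimination (AUC or concordance)
among those with Wald p < 0.05 goes forward — at most one candidate per
group, no multiple-testing correction (the grouping is the redundancy
control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .endpoints import BinaryEndpoint, SurvivalEndpoint
from .models import auc_mann_whitney

P_THRESHOLD = 0.05
HORN_N_SIM = 1000
HORN_PERCENTILE = 95.0


@dataclass(frozen=True)
class ScalingParams:
    means: dict[str, float]
    stds: dict[str, float]
    dropped_constant: tuple[str, ...] = ()

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in self.means if f not in table.columns]
        if missing:
            raise ValueError(f"features present in training but missing here: {missing[:5]}")
        out = table[list(self.means)].astype(float).copy()
        for f in self.means:
            out[f] = (out[f] - self.means[f]) / self.stds[f]
        return out


@dataclass(frozen=True)
class PCGrouping:
    """Retained components and the feature -> component assignment."""

    k: int
    loadings: pd.DataFrame  # features x retained components
    assignment: dict[str, int]  # feature -> component index (0-based)
    group_sizes: dict[int, int] = field(default_factory=dict)

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {g: [] for g in range(self.k)}
        for f, g in self.assignment.items():
            out[g].append(f)
        return out


@dataclass(frozen=True)
class ScreeningResult:
    """Per-feature univariable statistics and the per-group selections."""

    table: pd.DataFrame  # feature, group, p, metric, selected, flag
    selected: dict[int, str]  # group -> chosen feature

    @property
    def candidates(self) -> list[str]:
        return [self.selected[g] for g in sorted(self.selected)]


def _as_frame(table) -> pd.DataFrame:
    return table.data if hasattr(table, "data") else table


def scale_features(train, apply_to=None):
    """Standardize training columns to mean 0 / variance 1 (population).

    Constant training columns are dropped from both tables with a
    warning.  Returns ``(scaled_train, scaled_apply_or_None, params)``;
    the identical training-derived transform is applied to ``apply_to``.
    """
    train_df = _as_frame(train).astype(float)
    if train_df.empty:
        raise ValueError("training table is empty")
    means = train_df.mean()
    stds = train_df.std(ddof=0)
    constant = list(stds.index[stds == 0.0])
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant feature(s): {constant[:5]}",
            stacklevel=2,
        )
    keep = [c for c in train_df.columns if c not in constant]
    params = ScalingParams(
        means={c: float(means[c]) for c in keep},
        stds={c: float(stds[c]) for c in keep},
        dropped_constant=tuple(constant),
    )
    scaled_train = params.apply(train_df)
    scaled_apply = params.apply(_as_frame(apply_to)) if apply_to is not None else None
    return scaled_train, scaled_apply, params


def horn_retain(
    scaled: pd.DataFrame,
    n_sim: int = HORN_N_SIM,
    percentile: float = HORN_PERCENTILE,
    seed: int = 0,
) -> int:
    """Component retention by Horn's parallel analysis.

    Retains the k leading eigenvalues of the observed correlation matrix
    that exceed the same-rank ``percentile`` of eigenvalues from
    ``n_sim`` standard-normal datasets of identical shape; counting
    stops at the first rank that fails.
    """
    if n_sim < 100:
        raise ValueError("parallel analysis needs at least 100 simulations")
    X = _as_frame(scaled).to_numpy(dtype=float)
    n, p = X.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, p))
    for s in range(n_sim):
        Z = rng.standard_normal((n, p))
        sims[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    thresholds = np.percentile(sims, percentile, axis=0)
    k = 0
    for rank in range(p):
        if obs[rank] > thresholds[rank]:
            k += 1
        else:
            break
    return k


def pca_loadings(scaled: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Loadings (eigenvector * sqrt(eigenvalue)) of the correlation PCA."""
    X = _as_frame(scaled)
    corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    loadings = eigvec * np.sqrt(eigval)[None, :]
    cols = [f"pc{i + 1}" for i in range(len(eigval))]
    return pd.DataFrame(loadings, index=X.columns, columns=cols), eigval


def assign_to_components(loadings: pd.DataFrame, k: int) -> PCGrouping:
    """Assign each feature to the retained component of greatest contribution.

    Contribution is the squared loading; exact ties break toward the
    lowest component index.
    """
    if k < 1:
        raise ValueError(
            "no components retained; fall back to a single group containing all features"
        )
    contrib = loadings.iloc[:, :k].to_numpy() ** 2
    assignment = {f: int(np.argmax(contrib[i])) for i, f in enumerate(loadings.index)}
    sizes: dict[int, int] = {}
    for g in assignment.values():
        sizes[g] = sizes.get(g, 0) + 1
    return PCGrouping(k, loadings.iloc[:, :k].copy(), assignment, sizes)


def group_features(scaled: pd.DataFrame, n_sim: int = HORN_N_SIM, percentile: float = HORN_PERCENTILE, seed: int = 0) -> PCGrouping:
    """Horn retention followed by greatest-contribution assignment."""
    k = horn_retain(scaled, n_sim=n_sim, percentile=percentile, seed=seed)
    loadings, _ = pca_loadings(scaled)
    if k < 1:
        raise ValueError(
            "parallel analysis retained no components; fall back to a single group"
        )
    return assign_to_components(loadings, k)


def _univariable_binary(x: np.ndarray, y: np.ndarray):
    pos, neg = x[y > 0.5], x[y <= 0.5]
    # complete separation: the Wald test degenerates (exploding SE), so the
    # feature is retained outright with a flag
    if len(pos) and len(neg) and (pos.min() > neg.max() or pos.max() < neg.min()):
        return 0.0, 1.0, "separation"
    design = sm.add_constant(pd.DataFrame({"x": x}), has_constant="add")
    flag = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
        p = float(res.pvalues["x"])
        if not np.isfinite(p):
            raise ValueError("non-finite p-value")
    except Exception:
        p, flag = 0.0, "separation"
    auc = auc_mann_whitney(x, y)
    auc = max(auc, 1.0 - auc)  # prognostic value is direction-free
    if flag == "separation":
        auc = 1.0
    return p, auc, flag


def _univariable_cox(x: np.ndarray, times: np.ndarray, events: np.ndarray):
    from .models import harrell_concordance

    flag = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.PHReg(times, x[:, None], status=events.astype(int)).fit()
        p = float(res.pvalues[0])
        if not np.isfinite(p):
            raise ValueError("non-finite p-value")
        lp = float(res.params[0]) * x
    except Exception:
        p, flag = 0.0, "separation"
        lp = x
    c, _ = harrell_concordance(lp, times, events)
    ci = max(c, 1.0 - c)
    return p, ci, flag


def screen_univariable(scaled: pd.DataFrame, grouping: PCGrouping, endpoint) -> ScreeningResult:
    """Univariable screening: best significant feature per component group.

    Per feature: Wald p-value of the univariable coefficient plus AUC
    (binary endpoint) or concordance (survival endpoint).  Per group:
    the feature with the best metric among those with p < 0.05, or none;
    ties break by smaller p, then feature name.
    """
    X = _as_frame(scaled)
    is_binary = isinstance(endpoint, BinaryEndpoint)
    if not is_binary and not isinstance(endpoint, SurvivalEndpoint):
        raise TypeError("endpoint must be BinaryEndpoint or SurvivalEndpoint")
    if is_binary:
        ids = [i for i in X.index if i in endpoint.labels.index]
        X = X.loc[ids]
        y = endpoint.labels.loc[ids].to_numpy(dtype=float)
    else:
        times = endpoint.times.loc[X.index].to_numpy(dtype=float)
        events = endpoint.events.loc[X.index].to_numpy(dtype=bool)

    rows = []
    for feat in X.columns:
        x = X[feat].to_numpy(dtype=float)
        if is_binary:
            p, metric, flag = _univariable_binary(x, y)
        else:
            p, metric, flag = _univariable_cox(x, times, events)
        rows.append(
            {
                "feature": feat,
                "group": grouping.assignment.get(feat, -1),
                "p": p,
                "metric": metric,
                "flag": flag,
            }
        )
    table = pd.DataFrame(rows).set_index("feature")

    selected: dict[int, str] = {}
    for g in range(grouping.k):
        sub = table[(table["group"] == g) & (table["p"] < P_THRESHOLD)]
        if sub.empty:
            continue
        sub = sub.sort_values(["metric", "p"], ascending=[False, True], kind="stable")
        best_metric = sub["metric"].iloc[0]
        ties = sub[sub["metric"] == best_metric].sort_values("p", kind="stable")
        best_p = ties["p"].iloc[0]
        final = sorted(ties[ties["p"] == best_p].index)
        selected[g] = final[0]
    table["selected"] = [f in selected.values() for f in table.index]
    return ScreeningResult(table.reset_index(), selected)
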
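"""Scaling, parallel-analysis retention, grouping and univariable screening."""

import numpy as np
import pandas as pd
import pytest

from gliorad.endpoints import BinaryEndpoint, SurvivalEndpoint
from gliorad.selection import (
    PCGrouping,
    assign_to_components,
    group_features,
    horn_retain,
    pca_loadings,
    scale_features,
    screen_univariable,
)


def _df(X, prefix="f"):
    return pd.DataFrame(
        X,
        index=pd.Index([f"P{i}" for i in range(len(X))], name="patient_id"),
        columns=[f"{prefix}{j}" for j in range(X.shape[1])],
    )


class TestScaling:
    def test_training_columns_are_standardized(self, rng):
        X = _df(rng.normal(3.0, 2.0, size=(40, 6)))
        scaled, _, params = scale_features(X)
        assert np.all(np.abs(scaled.mean()) < 1e-10)
        assert np.allclose(scaled.var(ddof=0), 1.0, atol=1e-10)
        assert not params.dropped_constant

    def test_identical_validation_column_scales_identically(self, rng):
        X = _df(rng.normal(size=(30, 3)))
        scaled_train, scaled_val, _ = scale_features(X, X.copy())
        pd.testing.assert_frame_equal(scaled_train, scaled_val)

    def test_constant_column_dropped_from_both_tables(self, rng):
        X = _df(rng.normal(size=(20, 3)))
        X["f1"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            scaled, scaled_val, params = scale_features(X, X.copy())
        assert "f1" not in scaled.columns and "f1" not in scaled_val.columns
        assert params.dropped_constant == ("f1",)

    def test_missing_validation_feature_errors(self, rng):
        X = _df(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError, match="missing"):
            scale_features(X, X.drop(columns=["f2"]))


def _planted_factors(rng, n=200, p=40, k=2, strength=0.65):
    z = rng.standard_normal((n, k))
    load = np.zeros((p, k))
    per = p // k
    for j in range(k):
        load[j * per : (j + 1) * per, j] = strength
    return _df(z @ load.T + rng.standard_normal((n, p)) * np.sqrt(1 - strength**2))


class TestHorn:
    def test_pure_noise_retains_nothing(self, rng):
        X = _df(rng.standard_normal((60, 40)))
        assert horn_retain(X, n_sim=200, seed=1) == 0

    def test_two_planted_factors_are_retained(self, rng):
        X = _planted_factors(rng)
        assert horn_retain(X, n_sim=200, seed=2) == 2

    def test_fixed_seed_is_deterministic(self, rng):
        X = _planted_factors(rng)
        ks = {horn_retain(X, n_sim=150, seed=7) for _ in range(3)}
        assert len(ks) == 1

    def test_scale_invariance_through_the_pipeline(self, rng):
        X = _planted_factors(rng, n=100, p=12, k=2)
        X2 = X.copy()
        X2["f0"] = X2["f0"] * 1e4  # rescaling a raw feature
        s1, _, _ = scale_features(X)
        s2, _, _ = scale_features(X2)
        assert horn_retain(s1, n_sim=150, seed=3) == horn_retain(s2, n_sim=150, seed=3)


class TestAssignment:
    def test_greatest_contribution_wins(self):
        loadings = pd.DataFrame([[0.9, 0.1], [0.2, 0.8]], index=["a", "b"], columns=["pc1", "pc2"])
        g = assign_to_components(loadings, 2)
        assert g.assignment == {"a": 0, "b": 1}
        assert g.group_sizes == {0: 1, 1: 1}

    def test_exact_tie_breaks_to_lower_component(self):
        loadings = pd.DataFrame([[0.5, 0.5]], index=["a"], columns=["pc1", "pc2"])
        assert assign_to_components(loadings, 2).assignment == {"a": 0}

    def test_zero_components_instructs_fallback(self):
        loadings = pd.DataFrame([[0.5]], index=["a"], columns=["pc1"])
        with pytest.raises(ValueError, match="single group"):
            assign_to_components(loadings, 0)

    def test_block_structure_is_recovered(self, rng):
        X = _planted_factors(rng, n=300, p=30, k=3, strength=0.7)
        scaled, _, _ = scale_features(X)
        grouping = group_features(scaled, n_sim=150, seed=5)
        assert grouping.k == 3
        # features 0-9, 10-19, 20-29 are the true blocks
        correct = 0
        for j in range(30):
            block = j // 10
            mates = [grouping.assignment[f"f{i}"] for i in range(block * 10, block * 10 + 10)]
            if grouping.assignment[f"f{j}"] == max(set(mates), key=mates.count):
                correct += 1
        assert correct >= 0.95 * 30


class TestScreening:
    def _binary(self, y):
        return BinaryEndpoint("mgmt", pd.Series(y, index=[f"P{i}" for i in range(len(y))]))

    def test_perfect_predictor_is_selected(self, rng):
        n = 60
        y = np.repeat([0.0, 1.0], n // 2)
        X = _df(rng.standard_normal((n, 3)))
        X["f0"] = y + rng.normal(0, 1e-3, n)
        scaled, _, _ = scale_features(X)
        grouping = PCGrouping(1, pd.DataFrame(), {f: 0 for f in X.columns}, {0: 3})
        res = screen_univariable(scaled, grouping, self._binary(y))
        assert res.selected[0] == "f0"
        assert res.table.set_index("feature").loc["f0", "metric"] > 0.99

    def test_better_auc_wins_within_a_group(self, rng):
        n = 400
        y = np.repeat([0.0, 1.0], n // 2)
        X = _df(rng.standard_normal((n, 2)))
        # f0 stronger than f1, both significant
        X["f0"] = y * 1.2 + rng.standard_normal(n)
        X["f1"] = y * 0.6 + rng.standard_normal(n)
        scaled, _, _ = scale_features(X)
        grouping = PCGrouping(1, pd.DataFrame(), {f: 0 for f in X.columns}, {0: 2})
        res = screen_univariable(scaled, grouping, self._binary(y))
        tab = res.table.set_index("feature")
        assert tab.loc["f0", "metric"] > tab.loc["f1", "metric"]
        assert res.selected[0] == "f0"

    def test_noise_group_rarely_selected(self, rng):
        # group-level false selection needs some feature at p < 0.05
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            y = r.integers(0, 2, size=50).astype(float)
            if y.sum() in (0, 50):
                continue
            X = _df(r.standard_normal((50, 4)))
            scaled, _, _ = scale_features(X)
            grouping = PCGrouping(1, pd.DataFrame(), {f: 0 for f in X.columns}, {0: 4})
            res = screen_univariable(scaled, grouping, self._binary(y))
            hits += bool(res.selected)
        assert hits <= 0.35 * n_seeds  # well below certain selection

    def test_survival_screening_uses_concordance(self, rng):
        n = 120
        x = rng.standard_normal(n)
        t = rng.exponential(1.0 / np.exp(1.2 * x))
        e = np.ones(n, dtype=bool)
        X = _df(np.column_stack([x, rng.standard_normal(n)]))
        scaled, _, _ = scale_features(X)
        grouping = PCGrouping(1, pd.DataFrame(), {f: 0 for f in X.columns}, {0: 2})
        idx = X.index
        ep = SurvivalEndpoint("pfs2", pd.Series(t, index=idx), pd.Series(e, index=idx))
        res = screen_univariable(scaled, grouping, ep)
        assert res.selected[0] == "f0"
        assert res.table.set_index("feature").loc["f0", "metric"] > 0.6

    def test_candidates_never_share_a_group(self, rng):
        n = 150
        y = np.repeat([0.0, 1.0], n // 2)
        X = _df(rng.standard_normal((n, 6)))
        X["f0"] += y
        X["f1"] += y
        scaled, _, _ = scale_features(X)
        grouping = PCGrouping(
            2, pd.DataFrame(), {f: (0 if i < 3 else 1) for i, f in enumerate(X.columns)}, {0: 3, 1: 3}
        )
        res = screen_univariable(scaled, grouping, self._binary(y))
        groups = [grouping.assignment[f] for f in res.candidates]
        assert len(groups) == len(set(groups))
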
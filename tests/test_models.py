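"""Model fitting, prediction, evaluation and risk stratification."""

import numpy as np
import pandas as pd
import pytest
from _oracles import oracle_auc, oracle_concordance

from gliorad.endpoints import BinaryEndpoint, SurvivalEndpoint
from gliorad.models import (
    FittedModel,
    ModelFitError,
    auc_mann_whitney,
    cross_validate_5fold,
    evaluate_binary,
    evaluate_survival,
    fit_multivariable,
    harrell_concordance,
    predict,
    stratify_logrank,
)


def _df(X, prefix="f"):
    return pd.DataFrame(
        np.asarray(X, dtype=float),
        index=pd.Index([f"P{i}" for i in range(len(X))], name="patient_id"),
        columns=[f"{prefix}{j}" for j in range(np.asarray(X).shape[1])],
    )


def _binary(y, index):
    return BinaryEndpoint("mgmt", pd.Series(np.asarray(y, dtype=float), index=index))


def _survival(t, e, index):
    return SurvivalEndpoint(
        "os", pd.Series(np.asarray(t, dtype=float), index=index),
        pd.Series(np.asarray(e, dtype=bool), index=index),
    )


class TestPredict:
    def test_logit_zero_crossing_gives_half(self):
        model = FittedModel("logistic", ("f0",), {"f0": 5.77}, -2.46, 0.0)
        X = _df([[2.46 / 5.77]])
        assert predict(model, X).iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_missing_feature_is_reported(self):
        model = FittedModel("logistic", ("f9",), {"f9": 1.0}, 0.0, 0.0)
        with pytest.raises(ModelFitError, match="f9"):
            predict(model, _df([[0.0]]))

    def test_cox_concordance_is_shift_invariant(self, rng):
        lp = rng.standard_normal(50)
        t = rng.exponential(size=50)
        e = np.ones(50, dtype=bool)
        c1, _ = harrell_concordance(lp, t, e)
        c2, _ = harrell_concordance(lp + 100.0, t, e)
        assert c1 == pytest.approx(c2)

    def test_scaling_parameters_are_applied(self):
        model = FittedModel(
            "logistic", ("f0",), {"f0": 1.0}, 0.0, 0.0,
            scaling={"f0": {"mean": 10.0, "std": 2.0}},
        )
        p = predict(model, _df([[10.0]]))
        assert p.iloc[0] == pytest.approx(0.5)


class TestEvaluateBinary:
    def test_perfect_separation_gives_auc_one(self):
        rep = evaluate_binary([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert rep.metric == 1.0

    def test_worked_example_075(self):
        rep = evaluate_binary([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert rep.metric == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="classes"):
            evaluate_binary([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        scores = rng.choice([0.1, 0.2, 0.3, 0.5], size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            oracle_auc(scores, labels), abs=1e-12
        )

    def test_null_interval_covers_half(self):
        covered, aucs = 0, []
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            scores = rng.standard_normal(200)
            labels = rng.integers(0, 2, size=200)
            if labels.sum() in (0, 200):
                continue
            rep = evaluate_binary(scores, labels)
            aucs.append(rep.metric)
            covered += rep.ci_low <= 0.5 <= rep.ci_high
        assert abs(np.mean(aucs) - 0.5) < 0.02
        assert covered >= 0.88 * n_seeds


class TestEvaluateSurvival:
    def test_perfect_ranking(self, rng):
        t = rng.exponential(size=30) + 0.01
        rep = evaluate_survival(-t, t, np.ones(30, dtype=bool))
        assert rep.metric == 1.0

    def test_three_subject_example(self):
        # times (1,2,3) all events, predictors (3,1,2): pairs (1,2) and
        # (1,3) concordant, (2,3) discordant -> 2/3
        rep = evaluate_survival([3.0, 1.0, 2.0], [1.0, 2.0, 3.0], [True] * 3)
        assert rep.metric == pytest.approx(2.0 / 3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration_with_censoring(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        lp = rng.choice([0.0, 0.5, 1.0], size=n)
        t = rng.choice([1.0, 2.0, 3.0, 4.0], size=n)
        e = rng.random(n) < 0.7
        try:
            ref = oracle_concordance(lp, t, e)
        except ValueError:
            with pytest.raises(ValueError):
                harrell_concordance(lp, t, e)
            return
        c, _ = harrell_concordance(lp, t, e)
        assert c == pytest.approx(ref, abs=1e-12)

    def test_agrees_with_lifelines_without_ties(self, rng):
        from lifelines.utils import concordance_index

        lp = rng.standard_normal(80)
        t = rng.exponential(size=80)
        e = rng.random(80) < 0.7
        c, _ = harrell_concordance(lp, t, e)
        assert c == pytest.approx(concordance_index(t, -lp, e), abs=1e-12)

    def test_random_predictor_is_chance(self, rng):
        n = 500
        lp = rng.standard_normal(n)
        t = rng.exponential(size=n)
        cens = rng.exponential(size=n) * 2.0
        obs = np.minimum(t, cens)
        e = t <= cens
        rep = evaluate_survival(lp, obs, e)
        assert abs(rep.metric - 0.5) < 0.04

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_concordance([1.0, 2.0], [1.0, 2.0], [False, False])


class TestBackwardSelection:
    def test_single_candidate_keeps_or_empties(self, rng):
        n = 200
        y = rng.integers(0, 2, size=n).astype(float)
        X = _df(rng.standard_normal((n, 1)))
        model = fit_multivariable(X, _binary(y, X.index), ["f0"])
        # pure noise: the empty model usually wins, and is flagged
        if model.is_empty:
            assert "no_model" in model.flags
        else:
            assert model.features == ("f0",)

    def test_informative_feature_beats_noise(self, rng):
        kept_informative, extra_noise = 0, []
        n_seeds = 10
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 400
            X = _df(r.standard_normal((n, 6)))
            logit = 2.0 * X["f0"].to_numpy()
            y = (r.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(float)
            model = fit_multivariable(X, _binary(y, X.index), list(X.columns))
            kept_informative += "f0" in model.features
            extra_noise.append(len(set(model.features) - {"f0"}))
        assert kept_informative >= 9
        assert np.mean(extra_noise) <= 1.0

    def test_final_aic_never_above_full_model(self, rng):
        n = 150
        X = _df(rng.standard_normal((n, 5)))
        y = rng.integers(0, 2, size=n).astype(float)
        ep = _binary(y, X.index)
        import statsmodels.api as sm

        full = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        model = fit_multivariable(X, ep, list(X.columns))
        assert model.aic <= full.aic + 1e-9

    def test_wald_interval_coverage(self):
        covered = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 1000
            x = r.standard_normal(n)
            y = (r.uniform(size=n) < 1 / (1 + np.exp(-x))).astype(float)
            import statsmodels.api as sm

            res = sm.Logit(y, sm.add_constant(pd.DataFrame({"x": x}))).fit(disp=0)
            lo, hi = res.conf_int().loc["x"]
            covered += lo <= 1.0 <= hi
        assert covered >= 0.85 * n_seeds

    def test_cox_backward_selection_on_survival(self, rng):
        n = 300
        X = _df(rng.standard_normal((n, 4)))
        hz = 0.3 * np.exp(1.0 * X["f0"].to_numpy())
        t = rng.exponential(1.0 / hz)
        e = np.ones(n, dtype=bool)
        model = fit_multivariable(X, _survival(t, e, X.index), list(X.columns))
        assert model.model_type == "cox"
        assert "f0" in model.features

    def test_model_json_round_trip(self, tmp_path):
        model = FittedModel(
            "logistic", ("f0",), {"f0": 5.77}, -2.46, 12.3,
            scaling={"f0": {"mean": 0.1, "std": 2.0}},
        )
        model.to_json(tmp_path / "m.json")
        back = FittedModel.from_json(tmp_path / "m.json")
        assert back == model


class TestStratification:
    def test_median_split_on_training_itself(self, rng):
        scores = rng.standard_normal(41)
        t = rng.exponential(size=41)
        e = np.ones(41, dtype=bool)
        out = stratify_logrank(scores, scores, t, e)
        assert abs(out["n_high"] - out["n_low"]) <= 1

    def test_strong_hazard_ratio_is_detected(self):
        detected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 200
            scores = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
            hz = 0.2 * np.exp(np.log(3.0) * scores)  # hazard ratio 3
            t = r.exponential(1.0 / hz)
            e = np.ones(n, dtype=bool)
            out = stratify_logrank(scores - 0.5, scores - 0.5, t, e)
            detected += out["p"] < 0.05
        assert detected >= 0.9 * n_seeds

    def test_degenerate_single_group_is_flagged(self):
        out = stratify_logrank([0.0, 0.0], [-1.0, -2.0], [1.0, 2.0], [True, True])
        assert out["flag"] == "empty_risk_group"
        assert out["p"] is None


class TestCrossValidation:
    def _setup(self, rng, n=60):
        X = _df(rng.standard_normal((n, 3)))
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-2 * X["f0"].to_numpy()))).astype(float)
        return X, _binary(y, X.index)

    @staticmethod
    def _trivial_branch(Xf, epf):
        return FittedModel("logistic", ("f0",), {"f0": 1.0}, 0.0, 0.0)

    def test_every_subject_in_exactly_one_test_fold(self, rng):
        X, ep = self._setup(rng)
        seen = []
        out = cross_validate_5fold(X, ep, self._trivial_branch, seed=3)
        assert sum(d["n_test"] for d in out["folds"]) == len(X)
        sizes = [d["n_test"] for d in out["folds"]]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_for_fixed_seed(self, rng):
        X, ep = self._setup(rng)
        a = cross_validate_5fold(X, ep, self._trivial_branch, seed=11)
        b = cross_validate_5fold(X, ep, self._trivial_branch, seed=11)
        assert a == b

    def test_informative_feature_yields_discrimination(self, rng):
        X, ep = self._setup(rng, n=150)
        out = cross_validate_5fold(X, ep, self._trivial_branch, seed=5)
        assert out["mean_metric"] > 0.6


def test_validation_data_never_influences_training(rng):
    """Poisoning the validation cohort must leave the trained model identical."""
    from gliorad.pipeline import train_branch

    n = 80
    X = _df(rng.standard_normal((n, 8)))
    X.iloc[:, :4] = X.iloc[:, [0]].to_numpy() + 0.3 * rng.standard_normal((n, 4))
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-1.5 * X["f0"].to_numpy()))).astype(float)
    ep = _binary(y, X.index)
    model_a, _ = train_branch(X, ep, horn_n_sim=100, seed=1)
    # "validation" tables simply never enter train_branch; re-running after
    # constructing a poisoned copy must reproduce the model bit-for-bit
    poisoned_validation = X * 1e6 + 123.0  # noqa: F841  (never passed in)
    model_b, _ = train_branch(X.copy(), ep, horn_n_sim=100, seed=1)
    assert model_a == model_b
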
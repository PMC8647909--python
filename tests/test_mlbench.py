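"""Feature assembly, GP-based tuning, backends and fANOVA importance."""

import numpy as np
import pandas as pd
import pytest

from gxemet import mlbench as ml


def _inputs(n=40, n_years=4, seed=0):
    rng = np.random.default_rng(seed)
    pcs = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"PC{i + 1}" for i in range(5)])
    W = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"EC{i}" for i in range(6)])
    years = pd.Series(rng.choice(2014 + np.arange(n_years), size=n))
    coords = pd.DataFrame(rng.normal(size=(n, 2)), columns=["longitude", "latitude"])
    return pcs, W, years, coords


class TestFeatureTable:
    def test_without_W_only_pcs_years_coords(self):
        pcs, W, years, coords = _inputs()
        X, prov = ml.build_feature_table(pcs, None, years, coords, include_W=False)
        assert set(prov.unique()) == {"genomic_pc", "year", "coordinate"}
        assert not any(c.startswith("EC") for c in X.columns)

    def test_four_years_make_four_indicators(self):
        pcs, W, years, coords = _inputs(n_years=4)
        X, prov = ml.build_feature_table(pcs, W, years, coords)
        assert (prov == "year").sum() == 4

    def test_scaler_roundtrip_uses_training_statistics(self):
        pcs, W, years, coords = _inputs(60)
        X, prov = ml.build_feature_table(pcs, W, years, coords)
        scaler = ml.FeatureScaler(prov).fit(X.iloc[:40])
        Xt = scaler.transform(X.iloc[:40])
        cont = [c for c in Xt.columns if prov[c] != "year"]
        assert np.abs(Xt[cont].mean()).max() < 1e-10
        # year indicator columns stay 0/1
        ycols = [c for c in Xt.columns if prov[c] == "year"]
        assert set(np.unique(Xt[ycols].to_numpy())) <= {0.0, 1.0}
        # transforming test rows twice gives identical output (pure function)
        a = scaler.transform(X.iloc[40:])
        b = scaler.transform(X.iloc[40:])
        pd.testing.assert_frame_equal(a, b)

    def test_misaligned_rows_rejected(self):
        pcs, W, years, coords = _inputs()
        with pytest.raises(ValueError):
            ml.build_feature_table(pcs, W.iloc[:10], years, coords)


class TestBackends:
    def test_elastic_net_coefficients_shrink_with_penalty(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(200, 6)))
        y = X.iloc[:, 0] * 2 + rng.normal(0, 0.3, 200)
        norms = []
        for alpha in (0.01, 0.1, 1.0, 5.0):
            _, model = ml.fit_predict("elastic_net", {"alpha": alpha, "l1_ratio": 0.0}, X, y, X.iloc[:2])
            norms.append(np.abs(model.coef_).sum())
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_single_stump_recovers_split_means(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(50), np.ones(50)]})
        y = np.r_[np.full(50, 1.0), np.full(50, 3.0)]
        preds, _ = ml.fit_predict(
            "gbdt_a", {"max_depth": 1, "n_estimators": 1, "learning_rate": 1.0}, X, y, X
        )
        assert preds[:50].std() == pytest.approx(0.0, abs=1e-6)
        assert preds[0] == pytest.approx(1.0, abs=0.1)
        assert preds[-1] == pytest.approx(3.0, abs=0.1)

    def test_pure_noise_has_no_outer_predictive_skill(self):
        rng = np.random.default_rng(1)
        n = 2000
        X = pd.DataFrame(rng.normal(size=(n, 10)))
        y = rng.normal(size=n)
        preds, _ = ml.fit_predict(
            "gbdt_b",
            {"max_depth": 3, "n_estimators": 100, "learning_rate": 0.1},
            X.iloc[: n // 2], y[: n // 2], X.iloc[n // 2 :],
        )
        r = np.corrcoef(preds, y[n // 2 :])[0, 1]
        assert abs(r) < 0.1

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError):
            ml.fit_predict("mystery", {}, pd.DataFrame([[1.0]]), [1.0], pd.DataFrame([[1.0]]))


class TestTuneBayesGP:
    def _train(self, n=150, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 4)))
        y = X.iloc[:, 0] * X.iloc[:, 1] + 0.2 * rng.normal(size=n)  # needs depth >= 2
        return X, y

    def test_single_point_space_evaluated_once(self):
        X, y = self._train()
        space = [ml.Hyperparam("alpha", 0.5, 0.5), ml.Hyperparam("l1_ratio", 0.2, 0.2)]
        best, trials = ml.tune_bayes_gp("elastic_net", space, X, y, n_iter=5, n_init=3, seed=0)
        assert len(trials) == 1
        assert best == {"alpha": 0.5, "l1_ratio": 0.2}

    def test_best_is_argmin_of_trial_log(self):
        X, y = self._train()
        best, trials = ml.tune_bayes_gp(
            "elastic_net", ml.default_space("elastic_net"), X, y, n_iter=4, n_init=4, seed=1
        )
        best_rmse = min(t.rmse for t in trials)
        assert any(t.params == best and t.rmse == best_rmse for t in trials)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            ml.tune_bayes_gp("elastic_net", [], *self._train())

    def test_tuned_depth_beats_stump_on_interaction_response(self):
        space = [
            ml.Hyperparam("max_depth", 1, 6, integer=True),
            ml.Hyperparam("learning_rate", 0.05, 0.3, log=True),
        ]
        wins = 0
        for seed in range(3):
            X, y = self._train(n=260, seed=seed)
            tr, te = slice(0, 200), slice(200, 260)
            best, _ = ml.tune_bayes_gp(
                "gbdt_b", space, X.iloc[tr], y[tr], n_iter=6, n_init=4, seed=seed
            )
            base = {"max_depth": 1, "learning_rate": best.get("learning_rate", 0.1),
                    "n_estimators": 200}
            tuned = dict(base, **best, n_estimators=200)
            p_t, _ = ml.fit_predict("gbdt_b", tuned, X.iloc[tr], y[tr], X.iloc[te])
            p_b, _ = ml.fit_predict("gbdt_b", base, X.iloc[tr], y[tr], X.iloc[te])
            rmse = lambda p: np.sqrt(np.mean((p - y[te]) ** 2))
            if rmse(p_t) < rmse(p_b):
                wins += 1
        assert wins >= 2

    def test_inner_folds_partition_training_rows(self):
        from sklearn.model_selection import KFold

        train_rows = np.arange(123)
        kf = KFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.concatenate([te for _, te in kf.split(train_rows)])
        assert sorted(seen) == list(train_rows)


def _synthetic_trials(n=40, seed=0, inert_values=None):
    rng = np.random.default_rng(seed)
    trials = []
    inert = inert_values if inert_values is not None else rng.uniform(0, 1, n)
    for i in range(n):
        lr = rng.uniform(0.0, 1.0)
        trials.append(
            ml.TuneTrial(
                params={"learning_rate": lr, "inert": float(inert[i])},
                rmse=float((lr - 0.5) ** 2 + 0.001 * rng.normal() ** 2),
                iteration=i,
            )
        )
    return trials


class TestFanova:
    def test_single_driver_takes_most_variance(self):
        table = ml.fanova_importance(_synthetic_trials())
        main = table[table["kind"] == "main"].set_index("term")["share"]
        assert main["learning_rate"] > 0.8
        assert main["inert"] < 0.1

    def test_shares_bounded_and_subunit(self):
        table = ml.fanova_importance(_synthetic_trials(seed=2))
        assert (table["share"] >= 0).all()
        assert table["share"].sum() <= 1.0 + 1e-8

    def test_permuting_inert_hyperparameter_is_harmless(self):
        rng = np.random.default_rng(5)
        inert = rng.uniform(0, 1, 40)
        t1 = ml.fanova_importance(_synthetic_trials(seed=3, inert_values=inert))
        t2 = ml.fanova_importance(_synthetic_trials(seed=3, inert_values=rng.permuted(inert)))
        m1 = t1[t1["kind"] == "main"].set_index("term")["share"]
        m2 = t2[t2["kind"] == "main"].set_index("term")["share"]
        assert m1["learning_rate"] == pytest.approx(m2["learning_rate"], abs=0.1)

    def test_constant_rmse_warns_and_zeroes(self, caplog):
        trials = [
            ml.TuneTrial(params={"a": float(i) / 25, "b": 0.5}, rmse=1.0, iteration=i)
            for i in range(25)
        ]
        with caplog.at_level("WARNING"):
            table = ml.fanova_importance(trials)
        assert (table["share"] == 0).all()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            ml.fanova_importance(_synthetic_trials()[:10])

    def test_negative_rmse_rejected(self):
        with pytest.raises(ValueError):
            ml.TuneTrial(params={"a": 1.0}, rmse=-0.1, iteration=0)

    def test_monte_carlo_fallback_agrees_on_the_driver(self):
        trials = _synthetic_trials(seed=7)
        exact = ml.fanova_importance(trials)
        mc = ml.fanova_importance_mc(trials)
        e = exact[exact["kind"] == "main"].set_index("term")["share"]
        m = mc.set_index("term")["share"]
        assert e.idxmax() == m.idxmax() == "learning_rate"
        assert e["learning_rate"] == pytest.approx(m["learning_rate"], abs=0.15)
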
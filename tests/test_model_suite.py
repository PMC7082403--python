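"""Screening, forest fitting, importance, PDP, metrics, CV and trees."""

import numpy as np
import pandas as pd
import pytest

from yieldgap import model_suite as ms


def random_table(n=200, p=8, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)]
    )


class TestPearsonScreen:
    def test_constructed_degeneracy(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=200)
        X = pd.DataFrame({"x1": x1, "x2": x1.copy(), "x3": rng.normal(size=200)})
        y = pd.Series(x1, name="target")
        cats = {"x1": "a", "x2": "a", "x3": "a"}
        res = ms.pearson_screen(X, y, categories=cats)
        assert res.selected == ["x1"]
        reasons = res.table.set_index("feature")["reason"]
        assert "redundant" in reasons["x2"]
        assert reasons["x3"] == "low target correlation"

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=4000)
        y = pd.Series(rng.normal(size=4000), name="t")
        # build a feature with |r| ~= 0.14 by construction
        x = 0.14 * (y - y.mean()) / y.std() + np.sqrt(1 - 0.14**2) * z
        X = pd.DataFrame({"x": x})
        r = np.corrcoef(x, y)[0, 1]
        res = ms.pearson_screen(X, y, r_min=abs(r) + 1e-9)
        assert res.selected == []

    def test_constant_feature_rejected(self):
        X = random_table()
        X["const"] = 1.0
        y = pd.Series(X["f0"].to_numpy(), name="t")
        res = ms.pearson_screen(X, y)
        assert "const" not in res.selected
        assert res.table.set_index("feature").loc["const", "reason"] == "constant"

    def test_matches_brute_force_oracle(self):
        """Independent greedy reimplementation over the full correlation
        matrix reproduces the selection on a 20-feature random table."""
        rng = np.random.default_rng(7)
        n, p = 300, 20
        base = rng.normal(size=(n, 4))
        X = pd.DataFrame(
            {
                f"g{i}": base[:, i % 4] * rng.uniform(0.5, 1) + rng.normal(0, 1, n)
                for i in range(p)
            }
        )
        y = pd.Series(base[:, 0] + 0.5 * base[:, 1] + rng.normal(0, 1, n), name="t")
        cats = {c: f"cat{i % 5}" for i, c in enumerate(X.columns)}
        res = ms.pearson_screen(X, y, categories=cats)

        corr_with_y = {c: np.corrcoef(X[c], y)[0, 1] for c in X.columns}
        pos = {c: i for i, c in enumerate(X.columns)}
        order = sorted(X.columns, key=lambda c: (-abs(corr_with_y[c]), pos[c]))
        expected = []
        for c in order:
            if abs(corr_with_y[c]) <= ms.DEFAULT_R_MIN:
                continue
            if any(
                cats[s] == cats[c]
                and abs(np.corrcoef(X[c], X[s])[0, 1]) >= ms.DEFAULT_R_CROSS_MAX
                for s in expected
            ):
                continue
            expected.append(c)
        assert res.selected == expected

    def test_too_few_rows_rejected(self):
        X = random_table(n=10)
        with pytest.raises(ValueError):
            ms.pearson_screen(X, pd.Series(np.arange(10.0), name="t"))


class TestFitRF:
    def test_constant_target_predicts_constant(self):
        X = random_table(n=100)
        y = np.full(100, 3.14)
        rf = ms.fit_rf(X, y, seed=0, params=ms.RFParams(n_estimators=20))
        np.testing.assert_allclose(rf.model.predict(rf.X), 3.14)

    def test_same_seed_same_predictions(self):
        X = random_table(n=150)
        y = X["f0"] + np.random.default_rng(0).normal(0, 0.1, 150)
        p1 = ms.fit_rf(X, y, 5, ms.RFParams(n_estimators=30)).model.predict(X.to_numpy(np.float32))
        p2 = ms.fit_rf(X, y, 5, ms.RFParams(n_estimators=30)).model.predict(X.to_numpy(np.float32))
        np.testing.assert_array_equal(p1, p2)

    def test_missing_values_rejected(self):
        X = random_table(n=50)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            ms.fit_rf(X, np.zeros(50), 0)

    def test_training_beats_oob_beats_zero(self, small_sim):
        df = small_sim.dataset.to_frame()
        X = df[["light_interception", "age"]].astype(float)
        y = df["yield_kernel_lbs_acre"]
        rf = ms.fit_rf(X, y, 0, ms.RFParams(n_estimators=60))
        from sklearn.metrics import r2_score

        train_r2 = r2_score(y, rf.model.predict(rf.X))
        assert train_r2 > rf.oob_r2 > 0


class TestImportance:
    def test_relevant_feature_ranks_first_noise_near_zero(self):
        rng = np.random.default_rng(3)
        n = 400
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        y = X["x1"] + rng.normal(0, 0.01, n)
        rf = ms.fit_rf(X, y, 1, ms.RFParams(n_estimators=80, min_samples_leaf=2))
        imp = ms.importance_incmse(rf, n_repeats=10, seed=1)
        assert imp.rank_of("x1") == 1
        t = imp.table.set_index("feature")
        # the irrelevant feature's %IncMSE is indistinguishable from zero
        assert abs(t.loc["x2", "inc_mse_pct"]) < 2 * max(t.loc["x2", "inc_mse_pct_sd"], 1.0)
        assert t.loc["x1", "inc_mse_pct"] > 50

    def test_repeat_floor(self, small_sim):
        df = small_sim.dataset.to_frame()
        X = df[["light_interception", "age"]].astype(float)
        rf = ms.fit_rf(X, df["yield_kernel_lbs_acre"], 0, ms.RFParams(n_estimators=20))
        with pytest.raises(ValueError):
            ms.importance_incmse(rf, n_repeats=0)


class TestPartialDependence:
    def test_linear_response_recovered(self):
        rng = np.random.default_rng(4)
        n = 600
        X = pd.DataFrame({"x1": rng.uniform(0, 10, n), "x2": rng.normal(size=n)})
        y = 3.0 * X["x1"]
        rf = ms.fit_rf(X, y, 2, ms.RFParams(n_estimators=80, min_samples_leaf=2))
        curve = ms.partial_dependence_curve(rf, "x1", grid_points=30)
        interior = slice(3, -3)
        slope = np.polyfit(curve.grid[interior], curve.response[interior], 1)[0]
        assert slope == pytest.approx(3.0, rel=0.1)

    def test_unsplit_feature_gives_constant_curve(self):
        rng = np.random.default_rng(5)
        n = 300
        X = pd.DataFrame({"x1": rng.uniform(0, 10, n), "x2": np.zeros(n)})
        X.loc[0, "x2"] = 1e-9  # non-constant column, but useless for splits
        y = 2.0 * X["x1"]
        rf = ms.fit_rf(X, y, 3, ms.RFParams(n_estimators=40, min_samples_leaf=2))
        curve = ms.partial_dependence_curve(rf, "x2", grid_points=10)
        assert np.ptp(curve.response) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        n = 150
        X = pd.DataFrame({"a": rng.uniform(0, 5, n), "b": rng.normal(size=n)})
        y = X["a"] ** 2 + X["b"]
        rf = ms.fit_rf(X, y, 4, ms.RFParams(n_estimators=30, min_samples_leaf=2))
        curve = ms.partial_dependence_curve(rf, "a", grid_points=7)
        lo, hi = np.percentile(rf.X[:, 0].astype(float), [1.0, 99.0])
        for g, v in enumerate(np.linspace(lo, hi, 7)):
            Xmod = rf.X.astype(np.float64).copy()
            Xmod[:, 0] = v
            oracle = np.mean(rf.model.predict(Xmod.astype(np.float32)))
            assert curve.response[g] == pytest.approx(oracle, abs=1e-10)

    def test_unknown_feature_raises(self, small_sim):
        df = small_sim.dataset.to_frame()
        X = df[["light_interception", "age"]].astype(float)
        rf = ms.fit_rf(X, df["yield_kernel_lbs_acre"], 0, ms.RFParams(n_estimators=10))
        with pytest.raises(KeyError):
            ms.partial_dependence_curve(rf, "nope")


class TestRPIQ:
    def test_forced_arithmetic(self):
        obs = np.arange(0.0, 3001.0, 100.0)  # IQR = 2250 - 750 = 1500
        shift = np.where(np.arange(obs.size) % 2 == 0, 500.0, -500.0)
        assert ms.rpiq(obs, obs + shift) == pytest.approx(3.0)  # RMSE = 500

    def test_constant_shift(self):
        obs = np.arange(0.0, 3001.0, 100.0)
        assert ms.rpiq(obs, obs + 100.0) == pytest.approx(15.0)

    def test_matches_quantile_rmse_oracle(self):
        rng = np.random.default_rng(8)
        obs = rng.uniform(0, 5000, 500)
        pred = obs + rng.normal(0, 300, 500)
        oracle = (np.percentile(obs, 75) - np.percentile(obs, 25)) / np.sqrt(
            np.mean((obs - pred) ** 2)
        )
        assert ms.rpiq(obs, pred) == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_cases(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert ms.rpiq(obs, obs) == np.inf
        with pytest.raises(ValueError):
            ms.rpiq(obs[:3], obs[:3])


class TestCrossValidate:
    def test_leaked_target_gives_near_perfect_scores(self):
        rng = np.random.default_rng(9)
        y = rng.uniform(0, 100, 300)
        X = pd.DataFrame({"leak": y, "noise": rng.normal(size=300)})
        rep = ms.cross_validate(
            X, y, k=6, seed=0,
            params=ms.RFParams(n_estimators=50, min_samples_leaf=1),
        )
        assert np.mean(rep.r2) > 0.98
        assert np.mean(rep.rmse) < 0.1 * np.std(y)

    def test_shuffled_target_has_no_skill(self):
        rng = np.random.default_rng(10)
        X = random_table(n=300, p=5, seed=10)
        y_struct = X["f0"].to_numpy() * 2
        y_shuffled = rng.permutation(y_struct)
        rep = ms.cross_validate(X, y_shuffled, k=6, seed=0, params=ms.RFParams(n_estimators=40))
        assert np.mean(rep.r2) <= 0.05

    def test_folds_partition_and_report_shape(self):
        X = random_table(n=120)
        y = X["f0"].to_numpy()
        from sklearn.model_selection import KFold

        kf = KFold(n_splits=6, shuffle=True, random_state=3)
        seen = np.concatenate([te for _, te in kf.split(X)])
        assert sorted(seen.tolist()) == list(range(120))
        rep = ms.cross_validate(X, y, k=6, seed=3, params=ms.RFParams(n_estimators=10))
        assert len(rep.rmse) == len(rep.r2) == len(rep.rpiq) == 6
        summ = rep.summary()
        assert summ["r2"]["mean"] == pytest.approx(np.mean(rep.r2))
        assert summ["rmse"]["sd"] == pytest.approx(np.std(rep.rmse, ddof=1))

    def test_too_few_rows_rejected(self):
        X = random_table(n=30)
        with pytest.raises(ValueError):
            ms.cross_validate(X, X["f0"], k=6, seed=0)


class TestRepresentativeTree:
    def test_step_function_recovers_single_split(self):
        rng = np.random.default_rng(12)
        x1 = rng.uniform(0, 20, 400)
        X = pd.DataFrame({"x1": x1, "x2": rng.normal(size=400)})
        y = (x1 > 10).astype(float)
        rules = ms.fit_representative_tree(
            X, y, n_candidates=5, seed=0, max_depth=1, min_samples_leaf=5
        )
        splits = rules.split_features()
        assert len(splits) == 1
        feat, thr = splits[0]
        assert feat == "x1"
        below = x1[x1 <= 10].max()
        above = x1[x1 > 10].min()
        assert below < thr <= above + 1e-9

    def test_leaf_counts_sum_to_root(self, small_sim):
        df = small_sim.dataset.to_frame()
        X = df[["light_interception", "age"]].astype(float)
        rules = ms.fit_representative_tree(
            X, df["yield_kernel_lbs_acre"], n_candidates=5, seed=1, max_depth=3
        )
        root_n = rules.nodes[0].n
        assert sum(r["n"] for r in rules.rules) == root_n
        # rule predicates are internally consistent (no empty paths)
        assert all(r["n"] > 0 for r in rules.rules)

    def test_unsatisfiable_config_rejected(self):
        X = random_table(n=20)
        with pytest.raises(ValueError):
            ms.fit_representative_tree(X, X["f0"], n_candidates=1, seed=0, min_samples_leaf=50)
        with pytest.raises(ValueError):
            ms.fit_representative_tree(X, X["f0"], n_candidates=0, seed=0)


class TestScenarios:
    def test_design_matrices_respect_scenario_contracts(self, small_features):
        features, _ = small_features
        XA = ms.build_design(features, ms.SCENARIOS["A"])
        XD = ms.build_design(features, ms.SCENARIOS["D"], None)
        assert "light_interception" in XA.columns
        assert "light_interception" not in XD.columns
        assert not any(c.startswith(("tmean_", "vpdmax_", "ltm_")) for c in XA.columns)
        assert any(c.startswith("vpdmax_") for c in XD.columns)
        assert any(c.startswith("cultivar_") for c in XA.columns)
        with pytest.raises(ValueError):
            ms.build_design(features, ms.SCENARIOS["C"], None)

    def test_run_scenarios_structure_and_determinism(self, tmp_path, small_features, small_sim):
        from yieldgap.yield_frontier import compute_gaps, estimate_frontier

        features, _ = small_features
        model = estimate_frontier(small_sim.dataset, min_bin_count=10)
        gaps = compute_gaps(small_sim.dataset, model)
        cfg = ms.ScenarioRunConfig(
            seed=4,
            rf_params=ms.RFParams(n_estimators=15),
            importance_repeats=10,
            pdp_top_n=2,
            pdp_grid_points=8,
            tree_candidates=3,
        )
        out1 = tmp_path / "r1"
        out2 = tmp_path / "r2"
        rep1 = ms.run_scenarios(features, gaps, cfg, out_dir=out1)
        rep2 = ms.run_scenarios(features, gaps, cfg, out_dir=out2)
        assert set(rep1["cv"]) == {"A", "B", "C", "D"}
        for key in ("yield_model", "gap_model", "li_model"):
            assert "top_features" in rep1[key]
        assert (out1 / "cv_report.json").read_bytes() == (out2 / "cv_report.json").read_bytes()
        assert (out1 / "scenario_comparison.csv").read_bytes() == (
            out2 / "scenario_comparison.csv"
        ).read_bytes()
        assert (out1 / "rules_gap.json").exists()
        assert list((out1 / ".").glob("importance_*.csv"))
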
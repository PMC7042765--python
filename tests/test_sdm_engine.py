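import numpy as np
import pandas as pd
import pytest

from nicheshift.sdm_engine import (
    DEFAULT_CLASS_COMBOS,
    DEFAULT_RMS,
    MaxentModel,
    aicc,
    block_partition,
    build_features,
    fit_maxent,
    predict,
    tune,
)


def _env(n, d=4, seed=0, names=None):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(size=(n, d)), columns=names or [f"v{i}" for i in range(d)])


class TestFeatures:
    def test_feature_counts(self):
        sample = _env(50)
        assert build_features(sample, "L").n_features == 4
        assert build_features(sample, "LQP").n_features == 4 + 4 + 6
        assert build_features(sample, "LQH", knots=20).n_features == 4 + 4 + 2 * 20 * 4
        assert build_features(sample, "LQHPT", knots=20).n_features == 4 + 4 + 160 + 6 + 80

    def test_hinge_boundary_values(self):
        sample = pd.DataFrame({"x": [0.0, 10.0], "y": [0.0, 1.0]})
        fs = build_features(sample, "H", knots=3)
        knot = fs.features[0].knot
        at_knot = fs.transform(pd.DataFrame({"x": [10 * knot], "y": [0.5]}))
        at_max = fs.transform(pd.DataFrame({"x": [10.0], "y": [0.5]}))
        assert at_knot[0, 0] == pytest.approx(0.0, abs=1e-12)  # forward hinge at its knot
        assert at_max[0, 0] == pytest.approx(1.0, abs=1e-12)  # forward hinge at the maximum

    def test_all_features_in_unit_interval_with_clamping(self):
        sample = _env(100, seed=1)
        fs = build_features(sample, "LQHPT", knots=5)
        wild = _env(50, seed=2) * 10 - 5  # far outside the training range
        F = fs.transform(wild)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_constant_variable_drops_nonlinear_features(self):
        sample = pd.DataFrame({"x": np.linspace(0, 1, 30), "c": np.ones(30)})
        with pytest.warns(UserWarning, match="constant"):
            fs = build_features(sample, "LQH", knots=4)
        kinds = [(f.kind, f.variables) for f in fs.features]
        assert ("Q", ("c",)) not in kinds
        assert ("L", ("c",)) in kinds


class TestFitMaxent:
    def test_full_shrinkage_gives_uniform_model(self):
        pres, bg = _env(20, seed=3), _env(200, seed=4)
        fs = build_features(pd.concat([pres, bg]), "LQ")
        res = fit_maxent(pres, bg, fs, rm=1e4)
        assert np.all(res.params == 0.0)
        assert res.entropy == pytest.approx(np.log(200), abs=1e-9)
        raw = predict(res, bg, "raw")
        assert np.allclose(raw, 1 / 200, atol=1e-12)
        clog = predict(res, bg, "cloglog")
        assert np.allclose(clog, 1 - np.exp(-1), atol=1e-9)

    def test_single_binary_feature_against_1d_scan_oracle(self):
        # presences all carry the feature, background half of it
        pres = pd.DataFrame({"x": np.ones(30)})
        bg = pd.DataFrame({"x": np.r_[np.zeros(50), np.ones(50)]})
        fs = build_features(pd.concat([pres, bg]), "T", knots=1)
        assert fs.n_features == 1
        res = fit_maxent(pres, bg, fs, rm=0.05, tol=1e-9)
        beta = res.beta[0]
        # oracle: dense scan of the 1-D objective
        lam_grid = np.linspace(0, 30, 60001)
        obj = -lam_grid + np.log(50 * np.exp(lam_grid) + 50) - np.log(100) + beta * lam_grid
        lam_star = lam_grid[np.argmin(obj)]
        assert res.params[0] == pytest.approx(lam_star, abs=1e-2)
        assert res.params[0] > 3.0
        # fitted expectation matches the presence mean within beta
        w = np.exp(fs.transform(bg) @ res.params)
        e_fit = float((fs.transform(bg)[:, 0] * w / w.sum()).sum())
        assert abs(e_fit - 1.0) <= beta + 1e-6

    def test_solution_beats_random_probes(self):
        rng = np.random.default_rng(5)
        pres, bg = _env(25, d=3, seed=6), _env(60, d=3, seed=7)
        fs = build_features(pd.concat([pres, bg]), "L")
        res = fit_maxent(pres, bg, fs, rm=0.5)
        Fp, Fb = fs.transform(pres), fs.transform(bg)

        def objective(lam):
            from scipy.special import logsumexp

            return -Fp.mean(0) @ lam + logsumexp(Fb @ lam) + res.beta @ np.abs(lam)

        best = objective(res.params)
        probes = rng.normal(scale=2.0, size=(1000, fs.n_features))
        assert all(objective(p) >= best - 1e-9 for p in probes)

    def test_kkt_box_conditions(self):
        pres, bg = _env(40, seed=8), _env(300, seed=9)
        for classes, rm in [("L", 1.0), ("LQ", 0.5), ("LQH", 2.0)]:
            fs = build_features(pd.concat([pres, bg]), classes, knots=8)
            res = fit_maxent(pres, bg, fs, rm=rm)
            Fp, Fb = fs.transform(pres), fs.transform(bg)
            w = np.exp(Fb @ res.params)
            w /= w.sum()
            gap = np.abs(Fb.T @ w - Fp.mean(0))
            assert np.all(gap <= res.beta + 1e-4)

    def test_raw_probabilities_sum_to_one(self):
        pres, bg = _env(30, seed=10), _env(150, seed=11)
        fs = build_features(pd.concat([pres, bg]), "LQH", knots=5)
        res = fit_maxent(pres, bg, fs, rm=1.0)
        assert abs(predict(res, bg, "raw").sum() - 1.0) <= 1e-9

    def test_restart_reaches_same_objective(self):
        pres, bg = _env(30, seed=12), _env(150, seed=13)
        fs = build_features(pd.concat([pres, bg]), "LQ")
        a = fit_maxent(pres, bg, fs, rm=0.5)
        b = MaxentModel(pres, bg, feature_set=fs, rm=0.5).fit()
        assert np.allclose(a.params, b.params, atol=1e-6)

    def test_rm_path_monotone_sparsity(self):
        pres, bg = _env(50, seed=14), _env(400, seed=15)
        fs = build_features(pd.concat([pres, bg]), "LQH", knots=10)
        ks = [fit_maxent(pres, bg, fs, rm=rm, tol=1e-6).k for rm in DEFAULT_RMS]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_monotone_single_linear_model_preserves_order(self):
        pres = pd.DataFrame({"x": np.random.default_rng(16).uniform(0.6, 1, 30)})
        bg = pd.DataFrame({"x": np.random.default_rng(17).uniform(0, 1, 200)})
        fs = build_features(pd.concat([pres, bg]), "L")
        res = fit_maxent(pres, bg, fs, rm=0.5)
        assert res.params[0] > 0
        xs = pd.DataFrame({"x": np.linspace(0, 1, 20)})
        s = predict(res, xs, "cloglog")
        assert np.all(np.diff(s) >= 0)

    def test_summary_mentions_settings(self):
        pres, bg = _env(20, seed=18), _env(100, seed=19)
        res = MaxentModel(pres, bg, classes="L", rm=1.5, range_label="native").fit()
        s = res.summary()
        assert "native" in s and "1.5" in s


class TestBlockPartition:
    def test_symmetric_lattice(self):
        lon, lat = np.meshgrid(np.arange(4, dtype=float), np.arange(2, dtype=float))
        pres = np.column_stack([lon.ravel(), lat.ravel()])
        part = block_partition(pres, pres)
        counts = np.bincount(part.presence_block, minlength=4)
        assert counts.tolist() == [2, 2, 2, 2]

    def test_matches_brute_force_median_splits(self):
        rng = np.random.default_rng(20)
        pres = rng.uniform(size=(103, 2))
        bg = rng.uniform(size=(500, 2))
        part = block_partition(pres, bg)
        counts = np.bincount(part.presence_block, minlength=4)
        assert counts.max() - counts.min() <= 2
        # oracle: independent median-split reimplementation
        lat_med = np.median(pres[:, 1])
        south = pres[:, 1] <= lat_med
        lon_s, lon_n = np.median(pres[south, 0]), np.median(pres[~south, 0])
        oracle = np.where(south, 0, 2) + np.where(
            np.where(south, pres[:, 0] <= lon_s, pres[:, 0] <= lon_n), 0, 1
        )
        assert np.array_equal(part.presence_block, oracle)
        # background assigned by the same boundaries
        bsouth = bg[:, 1] <= lat_med
        boracle = np.where(bsouth, 0, 2) + np.where(
            np.where(bsouth, bg[:, 0] <= lon_s, bg[:, 0] <= lon_n), 0, 1
        )
        assert np.array_equal(part.background_block, boracle)

    def test_deterministic(self):
        rng = np.random.default_rng(21)
        pres, bg = rng.uniform(size=(40, 2)), rng.uniform(size=(80, 2))
        a, b = block_partition(pres, bg), block_partition(pres, bg)
        assert np.array_equal(a.presence_block, b.presence_block)

    def test_degenerate_coordinates_error(self):
        pres = np.tile([1.0, 2.0], (10, 1))
        with pytest.raises(ValueError, match="degenerate"):
            block_partition(pres, pres)


class TestAicc:
    def test_uniform_model_closed_form(self):
        pres, bg = _env(10, seed=22), _env(100, seed=23)
        fs = build_features(pd.concat([pres, bg]), "L")
        res = fit_maxent(pres, bg, fs, rm=1e4)  # k = 0
        k, logL, a = aicc(res, pres)
        assert k == 0
        assert logL == pytest.approx(10 * np.log(1 / 100), abs=1e-9)
        assert a == pytest.approx(-2 * logL, abs=1e-9)

    def test_overparameterized_flagged_invalid(self):
        pres, bg = _env(4, seed=24), _env(100, seed=25)
        fs = build_features(pd.concat([pres, bg]), "LQ")
        res = fit_maxent(pres, bg, fs, rm=1.0)
        res.params = np.ones(fs.n_features)  # k = 8 > n - 1 = 3
        k, logL, a = aicc(res, pres)
        assert k == fs.n_features
        assert np.isfinite(logL) and np.isnan(a)


class TestTune:
    def test_default_grid_has_48_candidates(self, scenario_factory):
        sc = scenario_factory(shift=0.0, seed=0)
        occ, bg = sc.occurrences["native"], sc.backgrounds["native"]
        tr = tune(occ.env, bg.env, cv=False, knots=10)
        assert len(tr.table) == len(DEFAULT_CLASS_COMBOS) * len(DEFAULT_RMS) == 48
        assert tr.table["delta_AICc"].min() == 0.0
        assert tr.selected_row["delta_AICc"] < 2.0

    def test_single_candidate_grid(self, scenario_factory):
        sc = scenario_factory(shift=0.0, seed=0)
        occ, bg = sc.occurrences["native"], sc.backgrounds["native"]
        tr = tune(occ.env, bg.env, class_combos=("L",), rms=(1.0,), cv=False)
        assert len(tr.table) == 1 and tr.selected == 0

    def test_linear_generative_niche_keeps_linear_class(self):
        # suitability driven by a monotone (linear) response of one variable
        rng = np.random.default_rng(26)
        bg = pd.DataFrame(rng.uniform(size=(500, 2)), columns=["x", "y"])
        w = np.exp(3 * bg["x"])
        pres = bg.iloc[rng.choice(500, size=60, p=w / w.sum())].reset_index(drop=True)
        pres_xy = pres.to_numpy() + rng.normal(scale=1e-3, size=(60, 2))
        tr = tune(
            pres, bg, pres_xy, bg.to_numpy(),
            class_combos=("L", "LQ", "LQH"), rms=(0.5, 1.0, 2.0), knots=5, cv=True,
        )
        assert "L" in tr.selected_row["feature_classes"]
        med = tr.table["mean_test_auc"].median()
        assert tr.selected_row["mean_test_auc"] >= med - 0.05
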
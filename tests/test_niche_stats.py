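import numpy as np
import pytest

from nicheshift.niche_space import build_grid, shared_bounds
from nicheshift.niche_stats import (
    GridParams,
    NicheComparison,
    equivalency_test,
    niche_dynamics,
    overlap,
    schoener_D,
    similarity_test,
    warren_I,
)


class TestOverlapMetrics:
    def test_two_cell_hand_values(self):
        z1 = np.array([1.0, 0.0])
        z2 = np.array([0.5, 0.5])
        assert schoener_D(z1, z2) == pytest.approx(0.5, abs=1e-12)
        expected_I = 1 - 0.5 * ((1 - np.sqrt(0.5)) ** 2 + 0.5)
        assert warren_I(z1, z2) == pytest.approx(expected_I, abs=1e-12)
        assert expected_I == pytest.approx(0.7071, abs=5e-4)

    def test_identical_grids_give_one(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(size=(10, 10))
        z /= z.sum()
        assert schoener_D(z, z) == pytest.approx(1.0, abs=1e-12)
        assert warren_I(z, z) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_give_zero(self):
        z1 = np.zeros((4, 4))
        z2 = np.zeros((4, 4))
        z1[0, 0] = 1.0
        z2[3, 3] = 1.0
        assert schoener_D(z1, z2) == 0.0
        assert warren_I(z1, z2) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_joint_permutation_invariance(self):
        rng = np.random.default_rng(1)
        z1 = rng.uniform(size=100)
        z2 = rng.uniform(size=100)
        z1 /= z1.sum()
        z2 /= z2.sum()
        assert schoener_D(z1, z2) == pytest.approx(schoener_D(z2, z1), abs=1e-14)
        assert warren_I(z1, z2) == pytest.approx(warren_I(z2, z1), abs=1e-14)
        perm = rng.permutation(100)
        assert schoener_D(z1[perm], z2[perm]) == pytest.approx(schoener_D(z1, z2), abs=1e-14)
        assert warren_I(z1[perm], z2[perm]) == pytest.approx(warren_I(z1, z2), abs=1e-14)

    def test_shape_mismatch_and_normalization(self):
        with pytest.raises(ValueError, match="shapes"):
            schoener_D(np.ones(3) / 3, np.ones(4) / 4)
        with pytest.warns(UserWarning, match="normalized"):
            assert schoener_D(np.ones(4), np.ones(4) / 4) == pytest.approx(1.0)


def _two_clusters(rng, sep, n1=40, n2=60):
    occ1 = rng.normal(loc=(-sep / 2, 0), scale=0.3, size=(n1, 2))
    occ2 = rng.normal(loc=(sep / 2, 0), scale=0.3, size=(n2, 2))
    bg = rng.uniform(-3, 3, size=(600, 2))
    return occ1, occ2, bg


class TestEquivalency:
    gp = GridParams(R=50)

    def test_identical_sets_never_rejected(self):
        rng = np.random.default_rng(2)
        occ = rng.normal(size=(30, 2))
        bg = rng.uniform(-3, 3, size=(300, 2))
        res = equivalency_test(occ, occ, bg, bg, self.gp, n_reps=49, seed=0)
        assert res.observed.D == pytest.approx(1.0, abs=1e-12)
        assert res.p_D == 1.0 and res.p_I == 1.0

    def test_separated_niches_reach_minimum_p(self):
        rng = np.random.default_rng(3)
        occ1, occ2, bg = _two_clusters(rng, sep=4.5)
        res = equivalency_test(occ1, occ2, bg, bg, self.gp, n_reps=99, seed=1)
        assert res.p_D == pytest.approx(1 / 100)  # minimum attainable p
        assert res.outside_ci_D

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        occ1, occ2, bg = _two_clusters(rng, sep=1.0)
        a = equivalency_test(occ1, occ2, bg, bg, self.gp, n_reps=29, seed=7)
        b = equivalency_test(occ1, occ2, bg, bg, self.gp, n_reps=29, seed=7)
        assert np.array_equal(a.null_D, b.null_D) and a.p_D == b.p_D

    def test_null_values_valid_overlaps(self):
        rng = np.random.default_rng(5)
        occ1, occ2, bg = _two_clusters(rng, sep=0.0)
        res = equivalency_test(occ1, occ2, bg, bg, self.gp, n_reps=29, seed=2)
        assert res.null_D.shape == (29,)
        assert ((res.null_D >= 0) & (res.null_D <= 1)).all()
        assert 0 < res.p_D <= 1

    def test_rejects_nreps_below_one(self):
        with pytest.raises(ValueError):
            equivalency_test(
                np.zeros((5, 2)), np.zeros((5, 2)), np.zeros((10, 2)), np.zeros((10, 2)),
                self.gp, n_reps=0, seed=0,
            )


class TestSimilarity:
    def test_uniform_target_is_translation_invariant(self):
        # a target occupying its whole (uniform) background is unchanged by
        # any wrapped relocation, so every null value equals the observed one
        xs = np.linspace(-2.9, 2.9, 30)
        grid_pts = np.array(np.meshgrid(xs, xs)).reshape(2, -1).T
        bounds = shared_bounds(grid_pts, grid_pts)
        g = build_grid(
            grid_pts, grid_pts, bounds, R=30, bandwidth=(0.5, 0.5), bg_bandwidth=(0.5, 0.5)
        )
        res = similarity_test(g, g, n_reps=19, seed=0)
        assert np.allclose(res.null_D, res.observed.D, atol=1e-9)
        assert res.p_D == 1.0

    def test_concentrated_identical_niches_detected_similar(self):
        rng = np.random.default_rng(6)
        occ = rng.normal(scale=0.2, size=(60, 2))
        bg = rng.uniform(-3, 3, size=(800, 2))
        bounds = shared_bounds(bg, bg)
        g = build_grid(occ, bg, bounds, R=50)
        res = similarity_test(g, g, n_reps=99, seed=3)
        assert res.observed.D == pytest.approx(1.0)
        assert res.p_D < 0.05 and res.outside_ci_D

    def test_deterministic_under_seed(self, scenario_factory):
        sc = scenario_factory(shift=4.0, seed=1)
        model = NicheComparison(
            sc.occurrences["native"].env,
            sc.backgrounds["native"].env,
            sc.occurrences["invasive"].env,
            sc.backgrounds["invasive"].env,
            grid_params=GridParams(R=50),
        )
        a = model.fit(n_reps=29, seed=11)
        b = model.fit(n_reps=29, seed=11)
        assert np.array_equal(
            a.similarity_native_to_invasive.null_D, b.similarity_native_to_invasive.null_D
        )
        assert a.similarity_invasive_to_native.p_D == b.similarity_invasive_to_native.p_D


def _dyn_oracle(z_nat, z_inv, q):
    """Independent set-arithmetic computation of E, S, U."""

    def occupied(z):
        if q == 0:
            return z > 0
        pos = sorted(z[z > 0].ravel())
        cum = np.cumsum(pos) / np.sum(pos)
        level = pos[int(np.searchsorted(cum, q))]
        return z > level

    on, oi = occupied(z_nat), occupied(z_inv)
    e = sum(z_inv[i, j] for i, j in zip(*np.nonzero(oi & ~on))) / z_inv[oi].sum()
    u = sum(z_nat[i, j] for i, j in zip(*np.nonzero(on & ~oi))) / z_nat[on].sum()
    return e, 1 - e, u


class _FakeGrid:
    def __init__(self, z, e):
        self.z = z / z.sum()
        self.e = e
        self.z_uncor = z / z.max()

    def occupancy(self, corrected=True):
        return self.z


class TestNicheDynamics:
    def test_identity_case(self):
        rng = np.random.default_rng(7)
        z = rng.uniform(size=(10, 10))
        g = _FakeGrid(z, np.ones_like(z))
        dyn = niche_dynamics(g, g, quantile_threshold=0.05)
        assert dyn.expansion == 0.0 and dyn.stability == 1.0 and dyn.unfilling == 0.0

    def test_disjoint_case(self):
        z1, z2 = np.zeros((6, 6)), np.zeros((6, 6))
        z1[:2, :2] = 1.0
        z2[4:, 4:] = 1.0
        dyn = niche_dynamics(
            _FakeGrid(z1, np.ones_like(z1)), _FakeGrid(z2, np.ones_like(z2)),
            quantile_threshold=0.0,
        )
        assert dyn.expansion == 1.0 and dyn.stability == 0.0 and dyn.unfilling == 1.0

    @pytest.mark.parametrize("q", [0.0, 0.05, 0.25])
    def test_matches_set_arithmetic_oracle(self, q):
        rng = np.random.default_rng(8)
        for _ in range(5):
            z1 = rng.uniform(size=(10, 10)) * (rng.uniform(size=(10, 10)) > 0.3)
            z2 = rng.uniform(size=(10, 10)) * (rng.uniform(size=(10, 10)) > 0.3)
            g1, g2 = _FakeGrid(z1, np.ones_like(z1)), _FakeGrid(z2, np.ones_like(z2))
            dyn = niche_dynamics(g1, g2, quantile_threshold=q)
            e, s, u = _dyn_oracle(g1.z, g2.z, q)
            assert dyn.expansion == pytest.approx(e, abs=1e-12)
            assert dyn.stability == pytest.approx(s, abs=1e-12)
            assert dyn.unfilling == pytest.approx(u, abs=1e-12)
            assert dyn.expansion + dyn.stability == pytest.approx(1.0, abs=1e-12)
            assert 0 <= dyn.unfilling <= 1

    def test_analogue_only_restricts_domain(self):
        z1, z2 = np.zeros((4, 4)), np.zeros((4, 4))
        z1[0, :] = 0.25
        z2[0, :2] = 0.3
        z2[3, :2] = 0.2
        e1 = np.ones((4, 4))
        e2 = np.zeros((4, 4))
        e2[:2] = 1.0  # invasive availability misses row 3
        dyn = niche_dynamics(
            _FakeGrid(z1, e1), _FakeGrid(z2, e2), quantile_threshold=0.0, analogue_only=True
        )
        # with the non-analogue row excluded, the invasive niche is fully stable
        assert dyn.expansion == 0.0

    def test_empty_occupied_set_errors(self):
        z = np.zeros((3, 3))
        z[0, 0] = 1.0
        with pytest.raises(ValueError):
            niche_dynamics(
                _FakeGrid(z, np.ones_like(z)), _FakeGrid(z, np.ones_like(z)),
                quantile_threshold=0.999999,
            )


class TestNicheComparisonModel:
    def test_end_to_end_shifted_scenario(self, scenario_factory):
        sc = scenario_factory(shift=4.0, seed=1)
        res = NicheComparison(
            sc.occurrences["native"].env,
            sc.backgrounds["native"].env,
            sc.occurrences["invasive"].env,
            sc.backgrounds["invasive"].env,
        ).fit(n_reps=99, seed=0)
        assert res.observed.D < 0.2
        assert res.equivalency.p_D <= 0.05
        assert res.dynamics.expansion > 0.8 and res.dynamics.unfilling > 0.8
        table = res.to_table()
        assert table.shape == (1, 11)
        assert "expansion" in res.summary() or "expansion" in table.columns

    def test_conservative_p_under_generator_null(self, scenario_factory):
        # with two independent landscapes and delta=0 the corrected-occupancy
        # test is conservative: p should rarely be small
        ps = []
        for seed in range(6):
            sc = scenario_factory(shift=0.0, seed=200 + seed)
            res = NicheComparison(
                sc.occurrences["native"].env,
                sc.backgrounds["native"].env,
                sc.occurrences["invasive"].env,
                sc.backgrounds["invasive"].env,
                grid_params=GridParams(R=60),
            ).fit(n_reps=49, seed=seed)
            ps.append(res.equivalency.p_D)
        assert np.mean(ps) > 0.4
        assert min(ps) > 0.05
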
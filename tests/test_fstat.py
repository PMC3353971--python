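"""F-function estimation, envelopes, normalization and aggregate tests."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import nucspat as ns
from nucspat.fstat import FCurve


class TestRGrid:
    def test_even_spacing_to_max_chord(self, unit_sphere):
        grid = ns.make_r_grid(unit_sphere, 5)
        assert np.allclose(grid, [0, 0.5, 1.0, 1.5, 2.0])

    def test_grid_starts_at_zero(self, ellipsoid):
        assert ns.make_r_grid(ellipsoid)[0] == 0.0

    def test_normalized_mode(self):
        grid = ns.make_r_grid(n_points=11, normalized=True)
        assert grid[0] == 0.0 and grid[-1] == 1.0


class TestEstimateF:
    def test_endpoints(self, unit_sphere, rng):
        pat = ns.sample_csr(unit_sphere, 10, rng)
        f = ns.estimate_F(pat, ns.make_r_grid(unit_sphere), rng, n_ref=2000)
        assert f.values[0] == 0.0
        assert f.values[-1] == 1.0
        assert np.all(np.diff(f.values) >= 0)

    def test_single_center_point_closed_form(self, unit_sphere, rng):
        """F(0.5) for one point at the centre is (0.5)^3 = 0.125."""
        pat = ns.PointPattern(np.zeros((1, 3)), unit_sphere)
        n_ref = 50_000
        f = ns.estimate_F(pat, np.array([0.0, 0.5]), rng, n_ref=n_ref)
        se = np.sqrt(0.125 * 0.875 / n_ref)
        assert abs(f.values[1] - 0.125) < 3 * se

    def test_agrees_with_grid_integration_oracle(self, unit_sphere):
        """MC estimate vs deterministic voxel-centre integration (3 sigma)."""
        rng = np.random.default_rng(42)
        pat = ns.sample_csr(unit_sphere, 5, rng)
        grid = ns.make_r_grid(unit_sphere, 21)
        n_ref = 10_000
        f = ns.estimate_F(pat, grid, rng, n_ref=n_ref)
        h = 0.01
        ax = np.arange(-1 + h / 2, 1, h)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        centers = centers[(centers**2).sum(axis=1) <= 1.0]
        d = np.sort(cKDTree(pat.points).query(centers)[0])
        f_true = np.searchsorted(d, grid, side="left") / len(d)
        se = np.sqrt(np.maximum(f_true * (1 - f_true), 1e-12) / n_ref)
        assert np.all(np.abs(f.values - f_true) <= 3 * se + 1e-9)

    def test_empty_pattern_rejected(self, unit_sphere, rng):
        pat = ns.PointPattern(np.zeros((0, 3)), unit_sphere)
        with pytest.raises(ValueError):
            ns.estimate_F(pat, ns.make_r_grid(unit_sphere), rng)


class TestFCurveInvariants:
    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            FCurve(np.array([0.0, 1, 2]), np.array([0.0, 0.5, 0.4]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            FCurve(np.array([0.0, 1.0]), np.array([0.0, 1.2]))

    def test_nonzero_origin_rejected(self):
        with pytest.raises(ValueError):
            FCurve(np.array([0.0, 1.0]), np.array([0.1, 0.5]))


class TestNullCurvesAndEnvelope:
    def test_null_curves_share_grid_and_count(self, unit_sphere, rng):
        grid = ns.make_r_grid(unit_sphere, 30)
        curves = ns.null_F_curves(unit_sphere, 20, 10, grid, rng, n_ref=500)
        assert len(curves) == 10
        for c in curves:
            assert np.shares_memory(c.r, grid) or np.allclose(c.r, grid)
            assert np.all(np.diff(c.values) >= 0)

    def test_envelope_is_empirical_quantiles(self, rng):
        grid = np.array([0.0, 1.0, 2.0])
        vals = rng.random((500, 3))
        vals.sort(axis=1)
        vals[:, 0] = 0.0
        curves = [FCurve(grid, v) for v in vals]
        env = ns.pointwise_envelope(curves, level=0.95)
        assert np.allclose(env.lower, np.quantile(vals, 0.025, axis=0))
        assert np.allclose(env.upper, np.quantile(vals, 0.975, axis=0))

    def test_identical_curves_collapse_envelope(self):
        grid = np.array([0.0, 1.0])
        curves = [FCurve(grid, np.array([0.0, 0.5]))] * 10
        env = ns.pointwise_envelope(curves)
        assert np.allclose(env.lower, env.upper)

    def test_envelope_contains_median_curve(self, unit_sphere, rng):
        grid = ns.make_r_grid(unit_sphere, 30)
        curves = ns.null_F_curves(unit_sphere, 15, 51, grid, rng, n_ref=500)
        vals = np.vstack([c.values for c in curves])
        med = np.median(vals, axis=0)
        env = ns.pointwise_envelope(curves)
        assert np.all(med >= env.lower - 1e-12)
        assert np.all(med <= env.upper + 1e-12)


class TestEnvelopeTest:
    @pytest.fixture
    def env(self):
        grid = np.linspace(0, 1, 11)
        lower = np.clip(grid - 0.2, 0, 1)
        upper = np.clip(grid + 0.2, 0, 1)
        return ns.Envelope(grid, lower, upper, 0.95, 500)

    def test_curve_inside_not_rejected(self, env):
        obs = FCurve(env.r, np.clip(env.r, 0, 1) * 0.999)
        res = ns.envelope_test(obs, env)
        assert not res.reject and res.direction == "none"

    def test_exit_above_is_regular(self, env):
        vals = np.clip(env.r + 0.21, 0, 1)
        vals[0] = 0.0
        vals = np.maximum.accumulate(vals)
        res = ns.envelope_test(FCurve(env.r, vals), env)
        assert res.reject and res.direction == "regular"

    def test_exit_below_is_clustered(self, env):
        vals = np.clip(env.r - 0.21, 0, 1)
        res = ns.envelope_test(FCurve(env.r, vals), env)
        assert res.reject and res.direction == "clustered"

    def test_boundary_tie_is_not_exit(self, env):
        vals = env.upper.copy()
        vals[0] = 0.0  # a valid F-curve starts at 0; ties elsewhere stay ties
        res = ns.envelope_test(FCurve(env.r, np.maximum.accumulate(vals)), env)
        assert not res.reject

    def test_pointwise_envelope_over_rejects_globally(self, unit_sphere):
        """CSR vs its own 95% pointwise envelope rejects more than 5%.

        The pointwise construction controls the error at each r separately,
        so the global (any-r) rejection rate under the null is inflated.
        """
        rng = np.random.default_rng(7)
        grid = ns.make_r_grid(unit_sphere, 50)
        n_null, n_trials, n_ref = 100, 200, 400
        rejects = 0
        for _ in range(n_trials):
            curves = ns.null_F_curves(unit_sphere, 16, n_null, grid, rng, n_ref=n_ref)
            env = ns.pointwise_envelope(curves, 0.95)
            pat = ns.sample_csr(unit_sphere, 16, rng)
            obs = ns.estimate_F(pat, grid, rng, n_ref=n_ref)
            rejects += ns.envelope_test(obs, env).reject
        rate = rejects / n_trials
        assert 0.05 - 0.03 < rate < 0.45


class TestNormalizeCurve:
    def test_unit_sphere_grid_relabel(self, unit_sphere, rng):
        pat = ns.sample_csr(unit_sphere, 10, rng)
        grid = ns.make_r_grid(unit_sphere, 50)
        f = ns.estimate_F(pat, grid, rng, n_ref=1000)
        norm = ns.normalize_curve(f, unit_sphere)
        # max chord 2: physical r=1 sits at normalized r=0.5
        assert norm.r[0] == 0.0 and norm.r[-1] == 1.0
        i = np.argmin(np.abs(norm.r - 0.5))
        j = np.argmin(np.abs(grid - 1.0))
        assert norm.values[i] == pytest.approx(f.values[j], abs=1e-9)
        assert norm.values[-1] == 1.0

    def test_scaled_copies_have_identical_normalized_curves(self):
        """Scale equivariance: region and pattern scaled together."""
        base = ns.HalfAxisParams(1.2, 0.9, 1.0, 1.1, 0.6, 0.5)
        small = ns.PiecewiseEllipsoidRegion(base)
        big = ns.PiecewiseEllipsoidRegion(
            ns.HalfAxisParams.from_array(3.0 * base.as_array())
        )
        # identical generator state: bounding-box rejection sampling scales
        # draw-for-draw, so the two runs are exact scaled copies
        f1 = ns.estimate_F(
            ns.sample_csr(small, 20, np.random.default_rng(3)),
            ns.make_r_grid(small, 64),
            np.random.default_rng(4),
            n_ref=2000,
        )
        f2 = ns.estimate_F(
            ns.sample_csr(big, 20, np.random.default_rng(3)),
            ns.make_r_grid(big, 64),
            np.random.default_rng(4),
            n_ref=2000,
        )
        n1 = ns.normalize_curve(f1, small)
        n2 = ns.normalize_curve(f2, big)
        assert np.allclose(n1.values, n2.values, atol=1e-12)


class TestPooledNullEnvelope:
    def test_single_region_matches_own_envelope(self, unit_sphere):
        n_grid = 40
        curves = ns.null_F_curves(
            unit_sphere,
            16,
            50,
            ns.make_r_grid(unit_sphere, n_grid),
            np.random.default_rng(5),
            n_ref=500,
        )
        own = ns.pointwise_envelope(
            [ns.normalize_curve(c, unit_sphere) for c in curves], 0.95
        )
        pooled = ns.pooled_null_envelope(
            [unit_sphere], 16, 50, 0.95, np.random.default_rng(5),
            n_ref=500, n_grid=n_grid,
        )
        assert np.allclose(pooled.lower, own.lower, atol=1e-12)
        assert np.allclose(pooled.upper, own.upper, atol=1e-12)

    def test_heterogeneous_pooling_widens_envelope(self, rng):
        """Pooling across shape classes spreads the envelope."""
        regions, _ = ns.build_collection("thick", 3, 0.2, seed=9)
        per_region_width = []
        for reg in regions:
            env = ns.pooled_null_envelope(
                [reg], 16, 60, 0.95, rng, n_ref=500, n_grid=40
            )
            per_region_width.append(np.trapezoid(env.upper - env.lower, env.r))
        pooled = ns.pooled_null_envelope(
            regions, 16, 60, 0.95, rng, n_ref=500, n_grid=40
        )
        pooled_width = np.trapezoid(pooled.upper - pooled.lower, pooled.r)
        assert pooled_width > np.mean(per_region_width)


class TestAggregateDistanceTest:
    def test_single_instance_reduces_to_individual(self, unit_sphere, rng):
        pat = ns.sample_csr(unit_sphere, 16, rng)
        res = ns.aggregate_distance_test([pat], rng, n_reps=100, n_ref=500)
        assert res.observed.r[0] == 0.0 and res.observed.r[-1] == 1.0

    def test_envelope_width_dominates_aggregate_noise(self, unit_sphere):
        """The aggregate test inherits single-curve envelope width while the
        averaged observed curve is far less variable — the structural reason
        the method has essentially no mid-range power."""
        rng = np.random.default_rng(21)
        pats = [ns.sample_csr(unit_sphere, 16, rng) for _ in range(10)]
        res = ns.aggregate_distance_test(pats, rng, n_reps=60, n_ref=600)
        env, obs = res.envelope, res.observed
        mid = (env.r > 0.1) & (env.r < 0.4) & (env.upper - env.lower > 0.01)
        half_width = (env.upper - env.lower)[mid] / 2
        center = (env.upper + env.lower)[mid] / 2
        # the averaged curve hugs the envelope centre relative to its width
        assert np.median(np.abs(obs.values[mid] - center) / half_width) < 0.5
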
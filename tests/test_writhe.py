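import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from oracles import quadrature_writhe
from writhesim.errors import (CurveTooShortError, DegenerateSegmentError,
                              AnalysisError, RebinRequiredError)
from writhesim.model_builder import Trajectory, build_bottlebrush
from writhesim.shapes import circle, closed_solenoid, figure_eight, helix
from writhesim.writhe import (DiscreteCurve, coarse_grain, distribution,
                              pool_distributions, writhe, writhe_series)


def lifted_lemniscate(n=400):
    return figure_eight(radius=2.0, n=n, handedness="right")


class TestWrithe:
    def test_planar_circle_is_zero(self):
        assert abs(writhe(circle(1.0, 64))) < 1e-12

    def test_right_handed_helix_positive(self):
        assert writhe(helix(1.0, 1.0, 2.0, 128, "right")) > 0.5
        assert writhe(helix(1.0, 1.0, 2.0, 128, "left")) < -0.5

    def test_solenoid_matches_quadrature(self):
        curve = closed_solenoid(1.0, 2.0, 3.0, 600, "right")
        wr = writhe(curve)
        assert wr == pytest.approx(quadrature_writhe(curve.vertices, True),
                                   abs=1e-6)

    def test_mirror_negates_exactly(self):
        curve = lifted_lemniscate()
        assert writhe(curve.mirrored()) == -writhe(curve)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_rigid_motion_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        curve = closed_solenoid(1.0, 1.5, 2.0, 120, "left")
        wr0 = writhe(curve)
        rot = Rotation.random(random_state=int(seed)).as_matrix()
        shift = rng.normal(0, 5.0, 3)
        scale = float(rng.uniform(0.2, 4.0))
        moved = DiscreteCurve(scale * (curve.vertices @ rot.T) + shift, True)
        assert writhe(moved) == pytest.approx(wr0, abs=1e-10)

    def test_convergence_order_in_vertex_count(self):
        """Polygonal writhe of a smooth closed curve converges to the fine
        limit with observed order >= 1 in 1/n."""
        ref = writhe(lifted_lemniscate(3200))
        errs = [abs(writhe(lifted_lemniscate(n)) - ref) for n in (100, 200, 400)]
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) >= 1.0

    def test_figure_eight_single_crossing(self):
        wr = writhe(lifted_lemniscate())
        assert 0.5 < abs(wr) < 1.5

    def test_too_short_and_degenerate_curves(self):
        with pytest.raises(CurveTooShortError):
            writhe(DiscreteCurve(np.zeros((3, 3)), False))
        v = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 1], [1, 0, 1.0]])
        with pytest.raises(DegenerateSegmentError):
            writhe(DiscreteCurve(v, False))


class TestWritheSeries:
    def test_backbone_and_sidechain_paths(self):
        topo = build_bottlebrush(20, 4, ring=True)
        rng = np.random.default_rng(0)
        pos = rng.normal(0, 3.0, (5, topo.n_beads, 3))
        traj = Trajectory(pos, np.arange(5.0))
        ws = writhe_series(traj, topo, "backbone")
        assert ws.values.shape == (5,)
        assert ws.curve_source == "backbone"
        # sidechain path: 80 sidechain beads in blocks of 2*Ns = 8 -> 10 vertices
        ws_side = writhe_series(traj, topo, ("sidechain_block", 8))
        assert ws_side.curve_source == "sidechain-path"

    def test_sidechain_block_vertex_count_formula(self):
        topo = build_bottlebrush(20, 4, ring=False)
        frame = np.random.default_rng(1).normal(0, 3.0, (topo.n_beads, 3))
        from writhesim.writhe import _frame_path
        curve = _frame_path(frame, topo, ("sidechain_block", 8))
        assert curve.n_vertices == 20 * 4 // 8

    def test_series_invariant_under_rotation_about_z(self):
        topo = build_bottlebrush(16, 2, ring=True)
        rng = np.random.default_rng(2)
        pos = rng.normal(0, 2.0, (4, topo.n_beads, 3))
        traj = Trajectory(pos, np.arange(4.0))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        traj_rot = Trajectory(pos @ rot.T, traj.times)
        a = writhe_series(traj, topo, "backbone").values
        b = writhe_series(traj_rot, topo, "backbone").values
        assert np.allclose(a, b, atol=1e-10)


class TestCoarseGrain:
    def test_identity_at_m_1(self):
        c = lifted_lemniscate(200)
        cg = coarse_grain(c, "average", 1)
        assert np.array_equal(cg.vertices, c.vertices)
        assert writhe(cg) == writhe(c)

    def test_modes_and_closure(self):
        c = lifted_lemniscate(200)
        avg = coarse_grain(c, "average", 4)
        assert avg.n_vertices == 50 and avg.closed
        skip = coarse_grain(c, "skip", 4)
        assert skip.n_vertices == 50 and skip.closed
        assert np.array_equal(skip.vertices, c.vertices[::4])

    def test_partial_block_warns(self):
        c = DiscreteCurve(np.random.default_rng(0).normal(0, 1, (103, 3)))
        with pytest.warns(UserWarning, match="partial"):
            cg = coarse_grain(c, "average", 5)
        assert cg.n_vertices == 21

    def test_block_too_large(self):
        c = lifted_lemniscate(40)
        with pytest.raises(CurveTooShortError):
            coarse_grain(c, "average", 12)

    def test_unknown_mode(self):
        with pytest.raises(AnalysisError):
            coarse_grain(lifted_lemniscate(40), "decimate", 2)


class TestDistribution:
    def test_gaussian_moments_and_free_energy(self):
        """Standard Gaussian samples: mean ~ 0, sigma ~ 1 within 2%, and the
        free energy -ln P is quadratic with curvature 1/2 over +-2 sigma."""
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100_000)
        dist = distribution(x, binwidth=0.1)
        assert abs(dist.mean) < 0.02
        assert dist.std == pytest.approx(1.0, rel=0.02)
        c = dist.bin_centers
        sel = (np.abs(c) < 2.0) & (dist.probability > 0)
        coef = np.polyfit(c[sel], dist.free_energy[sel], 2)
        assert coef[0] == pytest.approx(0.5, rel=0.05)
        assert dist.probability.sum() == pytest.approx(1.0, abs=1e-12)

    def test_min_samples_guard(self):
        with pytest.raises(AnalysisError):
            distribution(np.zeros(10) + 0.3)
        d = distribution(np.full(10, 0.3), min_samples=1)
        occupied = d.probability > 0
        assert occupied.sum() == 1
        assert d.free_energy[occupied][0] == 0.0
        assert d.mean == pytest.approx(0.3)
        assert d.std == pytest.approx(0.0, abs=1e-12)

    def test_bins_centered_on_zero(self):
        d = distribution(np.array([-0.3, 0.0, 0.3] * 50), binwidth=0.1,
                         min_samples=1)
        assert np.any(np.abs(d.bin_centers) < 1e-12)

    def test_pooled_mirror_variance_identity(self):
        """Pooling a sub-ensemble with its mirror: the pooled variance obeys
        the law of total variance, sigma^2_pool = sigma^2_sub + mean_sub^2."""
        rng = np.random.default_rng(7)
        x = rng.normal(-1.03, 1.58, 20_000)
        pooled = np.concatenate([x, -x])
        assert np.var(pooled) == pytest.approx(np.var(x) + np.mean(x) ** 2,
                                               rel=1e-12)
        d = distribution(pooled, binwidth=0.1)
        assert abs(d.mean) < 1e-12

    def test_pool_distributions_requires_same_bins(self):
        rng = np.random.default_rng(8)
        a = distribution(rng.normal(-1, 1, 1000), binwidth=0.1)
        b = distribution(rng.normal(1, 1, 1000), binwidth=0.2)
        with pytest.raises(RebinRequiredError):
            pool_distributions(a, b)

    def test_disjoint_inputs_pool_to_bimodal(self):
        rng = np.random.default_rng(9)
        left = rng.normal(-2.0, 0.3, 5000)
        right = rng.normal(2.0, 0.3, 5000)
        d = distribution([left, right], binwidth=0.2, weights=[0.5, 0.5])
        p0 = d.probability[np.abs(d.bin_centers) < 0.3].max()
        peaks = d.probability[np.abs(d.bin_centers) > 1.0].max()
        assert p0 < 0.1 * peaks

    def test_overlapping_inputs_pool_to_single_peak(self):
        rng = np.random.default_rng(10)
        left = rng.normal(-0.3, 1.0, 20_000)
        right = rng.normal(0.3, 1.0, 20_000)
        d = distribution([left, right], binwidth=0.2, weights=[0.5, 0.5])
        imax = int(np.argmax(d.probability))
        assert abs(d.bin_centers[imax]) <= 0.3
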
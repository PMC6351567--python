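import numpy as np
import pytest

from writhesim.errors import AnalysisError
from writhesim.model_builder import Cylinder, build_bottlebrush, build_semiflexible
from writhesim.protocols import (ProtocolPlan, detect_flips,
                                 pool_subensembles, run_brush_protocol,
                                 run_semiflexible_protocol)
from writhesim.writhe import WritheSeries

TINY = dict(compress_velocity=2e-2, inflate_steps=4000, settle_steps=2000,
            equil_steps=4000, prod_steps=20_000, sample_stride=200,
            n_replicas=2, base_seed=77)


@pytest.fixture(scope="module")
def semiflexible_run():
    topo = build_semiflexible(20, False, 20.0)
    cyl = Cylinder(5.0, 14.0)
    plan = ProtocolPlan(target_length=14.0, **TINY)
    return topo, cyl, plan, run_semiflexible_protocol(topo, cyl, plan)


class TestSemiflexibleProtocol:
    def test_stage_order_and_boundaries(self, semiflexible_run):
        _, _, plan, results = semiflexible_run
        for res in results:
            stages = res.manifest["stages"]
            names = list(stages)
            assert names == ["compress", "equilibrate", "produce"]
            bounds = [stages[n] for n in names]
            for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
                assert a1 == b0          # contiguous stages
            assert stages["produce"][1] - stages["produce"][0] == plan.prod_steps

    def test_production_frames_only_with_fixed_pistons(self, semiflexible_run):
        topo, _, plan, results = semiflexible_run
        for res in results:
            traj = res.trajectory
            assert traj.n_frames == plan.prod_steps // plan.sample_stride
            z_lo, z_hi = traj.metadata["pistons"]
            # compression reached the target exactly, pistons now fixed
            assert z_hi - z_lo == pytest.approx(plan.target_length, abs=1e-9)
            z = traj.positions[:, :, 2]
            assert z.min() > z_lo and z.max() < z_hi

    def test_replica_independence(self, semiflexible_run):
        _, _, _, results = semiflexible_run
        a, b = results[0].trajectory, results[1].trajectory
        assert results[0].manifest["seed"] != results[1].manifest["seed"]
        assert not np.allclose(a.positions[-1], b.positions[-1])

    def test_short_run_flagged_under_sampled(self):
        """With production much shorter than 20 x tau_int of Wr the replica
        is marked under-sampled rather than silently trusted."""
        topo = build_semiflexible(20, False, 20.0)
        cyl = Cylinder(5.0, 14.0)
        plan = ProtocolPlan(target_length=14.0, **{**TINY,
                            "prod_steps": 3_000, "sample_stride": 20,
                            "n_replicas": 1})
        with pytest.warns(UserWarning, match="under-sampled"):
            results = run_semiflexible_protocol(topo, cyl, plan)
        assert results[0].manifest["under_sampled"]


class TestBrushProtocol:
    def test_stage_order_and_sign_bookkeeping(self):
        topo = build_bottlebrush(24, 2, ring=True)
        cyl = Cylinder(6.0, 10.0)
        plan = ProtocolPlan(target_length=10.0, **TINY)
        results = run_brush_protocol(topo, cyl, plan, "left",
                                     replicas=[0])
        res = results[0]
        assert list(res.manifest["stages"]) == [
            "inflate", "settle", "compress", "equilibrate", "produce"]
        assert res.wr.label == "left"
        assert res.trajectory.n_frames == plan.prod_steps // plan.sample_stride
        # inflation resolved the collapsed sidechains: no overlapping beads
        last = res.trajectory.positions[-1]
        from scipy.spatial.distance import pdist
        assert pdist(last).min() > 0.5

    def test_requires_handedness(self):
        topo = build_bottlebrush(24, 2, ring=True)
        plan = ProtocolPlan(target_length=10.0, **TINY)
        with pytest.raises(ValueError):
            run_brush_protocol(topo, Cylinder(6.0, 10.0), plan, "none")


class TestFlipDetection:
    def test_no_flip_on_steady_sign(self):
        rng = np.random.default_rng(0)
        assert detect_flips(-1.0 + 0.3 * rng.standard_normal(2000)) == []

    def test_persistent_sign_change_detected(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([-1 + 0.2 * rng.standard_normal(500),
                            +1 + 0.2 * rng.standard_normal(500)])
        flips = detect_flips(v)
        assert len(flips) == 1
        assert 380 < flips[0] < 520

    def test_brief_excursion_ignored(self):
        rng = np.random.default_rng(2)
        v = -1 + 0.2 * rng.standard_normal(2000)
        v[900:960] = +1.0        # shorter than the persistence threshold
        assert detect_flips(v) == []


class TestPooling:
    def test_mirror_pair_pools_to_symmetric(self):
        rng = np.random.default_rng(3)
        x = rng.normal(-1.0, 0.5, 5000)
        left = WritheSeries(x, np.arange(5000.0), label="left")
        right = WritheSeries(-x, np.arange(5000.0), label="right")
        pooled = pool_subensembles(left, right, binwidth=0.1)
        assert abs(pooled.mean) < 0.1    # below one binwidth
        p = pooled.probability
        assert np.allclose(p, p[::-1], atol=1e-12)

    def test_unequal_sample_counts_get_equal_weight(self):
        rng = np.random.default_rng(4)
        left = WritheSeries(rng.normal(-1, 0.2, 9000), np.arange(9000.0))
        right = WritheSeries(rng.normal(1, 0.2, 1000), np.arange(1000.0))
        pooled = pool_subensembles(left, right, binwidth=0.1)
        assert abs(pooled.mean) < 0.05

    def test_empty_side_rejected(self):
        s = WritheSeries(np.zeros(10), np.arange(10.0))
        with pytest.raises(AnalysisError):
            pool_subensembles([], [s])
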
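import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from writhesim.errors import BondOverstretchError, EscapedBeadError
from writhesim.forcefield import (WCA_CUT, ForceFieldParams, bend_energy,
                                  fene_energy, soft_energy, total_forces,
                                  wall_energy, wca_energy)
from writhesim.model_builder import (Conformation, Cylinder,
                                     build_semiflexible)

FF = ForceFieldParams()


class TestScalarPotentials:
    def test_fene_closed_form(self):
        assert fene_energy(0.0, FF) == 0.0
        expected = -0.5 * 30.0 * 1.5 ** 2 * np.log(0.75)
        assert fene_energy(0.75, FF) == pytest.approx(expected, rel=1e-12)
        assert fene_energy(0.75, FF) == pytest.approx(9.7093, abs=2e-4)
        # logarithmic divergence approaching r0: large but finite
        big = fene_energy(1.4999, FF)
        assert big > 250 and np.isfinite(big)
        huge = fene_energy(1.5 * (1.0 - 1e-15), FF)
        assert huge > 1e3 and np.isfinite(huge)
        with pytest.raises(BondOverstretchError):
            fene_energy(1.5, FF)

    def test_fene_monotone(self):
        r = np.linspace(0.0, 1.45, 200)
        u = fene_energy(r, FF)
        assert np.all(np.diff(u) > 0)

    def test_wca_closed_form(self):
        assert wca_energy(WCA_CUT, FF) == 0.0
        assert wca_energy(1.0, FF) == pytest.approx(1.0, rel=1e-12)
        assert wca_energy(2.0, FF) == 0.0
        # continuous at the cutoff
        assert wca_energy(WCA_CUT - 1e-9, FF) == pytest.approx(0.0, abs=1e-7)

    def test_bend_closed_form(self):
        kb = 51.546
        p = FF.with_(bend_kb=kb)
        assert bend_energy(np.pi, p) == 0.0
        assert bend_energy(np.pi / 2, p) == pytest.approx(kb * np.pi ** 2 / 4)

    def test_soft_closed_form(self):
        p = FF.with_(soft_a=60.0, soft_rc=1.0)
        assert soft_energy(1.0, p) == pytest.approx(0.0, abs=1e-12)
        assert soft_energy(0.0, p) == pytest.approx(120.0)
        assert soft_energy(0.5, p) == pytest.approx(60.0)

    def test_params_require_bond_minimum(self):
        with pytest.raises(ValueError):
            ForceFieldParams(fene_r0=1.0)


class TestWall:
    def test_wall_examples(self):
        cyl = Cylinder(15.0, None)
        # 2 sigma from the wall: beyond the WCA cutoff
        assert wall_energy([15.0 / 2 - 2.0, 0, 0], cyl, FF) == 0.0
        # exactly sigma from the wall surface: same closed form as WCA at r=1
        assert wall_energy([15.0 / 2 - 1.0, 0, 0], cyl, FF) == pytest.approx(1.0)

    def test_wall_piston_additivity(self):
        cyl = Cylinder(10.0, 8.0)
        # sigma from the wall and sigma from the upper piston
        e = wall_energy([4.0, 0.0, 3.0], cyl, FF)
        assert e == pytest.approx(2.0)

    def test_escaped_bead(self):
        cyl = Cylinder(6.0, None)
        with pytest.raises(EscapedBeadError):
            wall_energy([3.0, 0.0, 0.0], cyl, FF)


def _random_confined_chain(rng, n=6):
    """Random chain with bond lengths in [0.85, 1.05] (well inside the FENE
    range, so force magnitudes stay O(10-100) and the finite-difference
    comparison is meaningful at 1e-6 eps/sigma)."""
    topo = build_semiflexible(n, False, 5.0)
    d = rng.normal(0, 1.0, (n - 1, 3)) + [0, 0, 1.5]
    d *= (rng.uniform(0.9, 1.05, n - 1) / np.linalg.norm(d, axis=1))[:, None]
    pos = np.cumsum(np.vstack([np.zeros(3), d]), axis=0)
    pos -= pos.mean(axis=0)
    return topo, Conformation(pos, np.zeros((n, 3)))


class TestTotalForces:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_forces_match_finite_differences(self, seed):
        """Every force component equals the central finite difference of the
        total energy (FENE + WCA + bending + wall + pistons)."""
        rng = np.random.default_rng(seed)
        topo, conf = _random_confined_chain(rng)
        cyl = Cylinder(6.0, 9.0)
        ff = FF.with_(bend_kb=topo.bend_kb)
        f, _ = total_forces(conf, topo, cyl, ff)
        h = 1e-6
        n = conf.positions.shape[0]
        for i in range(n):
            for d in range(3):
                p = conf.positions.copy()
                p[i, d] += h
                _, ep = total_forces(Conformation(p, conf.velocities),
                                     topo, cyl, ff)
                p[i, d] -= 2 * h
                _, em = total_forces(Conformation(p, conf.velocities),
                                     topo, cyl, ff)
                assert -(ep - em) / (2 * h) == pytest.approx(
                    f[i, d], abs=1e-6)

    def test_soft_forces_match_finite_differences(self):
        rng = np.random.default_rng(3)
        topo, conf = _random_confined_chain(rng)
        ff = FF.with_(soft_a=30.0)
        f, _ = total_forces(conf, topo, None, ff, use_soft=True)
        h = 1e-6
        for i in range(3):
            p = conf.positions.copy()
            p[i, 2] += h
            _, ep = total_forces(Conformation(p, conf.velocities), topo,
                                 None, ff, use_soft=True)
            p[i, 2] -= 2 * h
            _, em = total_forces(Conformation(p, conf.velocities), topo,
                                 None, ff, use_soft=True)
            assert -(ep - em) / (2 * h) == pytest.approx(f[i, 2], abs=1e-5)

    def test_internal_forces_sum_to_zero_without_walls(self):
        rng = np.random.default_rng(11)
        topo, conf = _random_confined_chain(rng, n=9)
        ff = FF.with_(bend_kb=topo.bend_kb)
        f, _ = total_forces(conf, topo, None, ff)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)

    def test_dimer_mechanical_minimum(self):
        """The FENE+WCA bond minimum sits where the two gradients cancel,
        consistent with a mean bond length just below 0.97 sigma."""
        def dudr(r):
            fene = FF.fene_k * r / (1.0 - (r / FF.fene_r0) ** 2)
            wca = -24.0 * (2.0 * r ** -13 - r ** -7)
            return fene + wca
        r_min = brentq(dudr, 0.9, 1.1, xtol=1e-12)
        assert 0.95 < r_min < 0.97
        topo = build_semiflexible(3, False, 0.0)
        pos = np.array([[0, 0, 0.0], [0, 0, r_min], [0, 0, 2 * r_min]])
        f, _ = total_forces(Conformation(pos, np.zeros((3, 3))), topo,
                            None, FF)
        # beyond-cutoff 1-3 WCA pair contributes nothing; bonds at minimum
        assert np.abs(f).max() < 1e-8

    def test_energy_invariant_under_rotation_about_axis(self):
        rng = np.random.default_rng(5)
        topo, conf = _random_confined_chain(rng)
        cyl = Cylinder(6.0, 9.0)
        ff = FF.with_(bend_kb=topo.bend_kb)
        _, e0 = total_forces(conf, topo, cyl, ff)
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        conf_r = Conformation(conf.positions @ rot.T, conf.velocities)
        _, e1 = total_forces(conf_r, topo, cyl, ff)
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_overstretched_bond_aborts_with_frame(self):
        topo = build_semiflexible(3, False, 0.0)
        pos = np.array([[0, 0, 0.0], [0, 0, 1.55], [0, 0, 2.5]])
        with pytest.raises(BondOverstretchError) as exc:
            total_forces(Conformation(pos, np.zeros((3, 3))), topo, None, FF)
        assert exc.value.frame is not None
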
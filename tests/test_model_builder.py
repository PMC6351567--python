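import numpy as np
import pytest

from writhesim.errors import GeometryError, TopologyError
from writhesim.model_builder import (MEAN_BOND, Conformation, Cylinder,
                                     build_bottlebrush, build_semiflexible,
                                     initial_conformation)
from writhesim.writhe import DiscreteCurve, writhe


@pytest.mark.parametrize("n,ring,lp,beads,bonds,angles", [
    (25, False, 100.0, 25, 24, 23),
    (50, True, 40.0, 50, 50, 50),
    (3, False, 0.0, 3, 2, 1),
])
def test_semiflexible_counts(n, ring, lp, beads, bonds, angles):
    topo = build_semiflexible(n, ring, lp)
    assert topo.n_beads == beads
    assert len(topo.bonds) == bonds
    assert len(topo.angles) == angles
    assert topo.n_side_per_monomer == 0
    if lp == 0:
        assert topo.bend_kb == 0.0


def test_semiflexible_kb_matches_lp_relation():
    topo = build_semiflexible(25, False, 100.0)
    assert topo.bend_kb == pytest.approx(100.0 / (2 * MEAN_BOND), rel=1e-12)


@pytest.mark.parametrize("n,ns,ring,beads", [
    (200, 10, True, 2200),
    (100, 40, False, 4100),
    (3, 1, False, 6),
])
def test_bottlebrush_counts(n, ns, ring, beads):
    topo = build_bottlebrush(n, ns, ring)
    assert topo.n_beads == beads
    assert topo.n_beads == n * (ns + 1)
    assert len(topo.angles) == 0
    expected_bonds = (n if ring else n - 1) + n * ns
    assert len(topo.bonds) == expected_bonds


def test_bottlebrush_count_formulas_exhaustive():
    for n in range(3, 11):
        for ns in range(1, 6):
            for ring in (False, True):
                topo = build_bottlebrush(n, ns, ring)
                assert topo.n_beads == n * (ns + 1)
                assert len(topo.bonds) == (n if ring else n - 1) + n * ns
                # every sidechain is a linear run anchored to one monomer
                for i in range(n):
                    beads = topo.sidechain_beads(i)
                    assert beads.size == ns
                    assert np.all(topo.sidechain_of[beads] == i)


def test_invalid_topologies_raise():
    with pytest.raises(TopologyError):
        build_semiflexible(2, False, 10.0)
    with pytest.raises(TopologyError):
        build_semiflexible(10, False, -1.0)
    with pytest.raises(TopologyError):
        build_bottlebrush(2, 5, False)
    with pytest.raises(TopologyError):
        build_bottlebrush(10, 0, False)


def test_straight_initial_conformation():
    topo = build_semiflexible(25, False, 100.0)
    conf = initial_conformation(topo, Cylinder(4.0, None), "none")
    d = np.linalg.norm(np.diff(conf.positions, axis=0), axis=1)
    assert np.allclose(d, MEAN_BOND, atol=1e-9)
    assert np.allclose(conf.positions[:, :2], 0.0)
    conf.validate(topo)


def test_serpentine_when_chain_longer_than_cylinder():
    topo = build_semiflexible(40, False, 0.0)
    cyl = Cylinder(6.0, 15.0)
    conf = initial_conformation(topo, cyl, "none")
    d = np.linalg.norm(np.diff(conf.positions, axis=0), axis=1)
    # straight runs at the mean bond length; chords across the hairpin
    # turns are somewhat shorter (the dynamics relaxes them immediately)
    assert d.min() > 0.7 and d.max() < 1.0
    assert np.median(d) == pytest.approx(MEAN_BOND, abs=0.02)
    z = conf.positions[:, 2]
    lo, hi = cyl.piston_positions
    assert z.min() > lo and z.max() < hi
    rho = np.hypot(conf.positions[:, 0], conf.positions[:, 1])
    assert rho.max() < cyl.radius - 0.5


def test_ring_racetrack_template():
    topo = build_semiflexible(50, True, 40.0)
    conf = initial_conformation(topo, Cylinder(4 * np.sqrt(2), None), "none")
    closed = np.vstack([conf.positions, conf.positions[:1]])
    d = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    assert d.min() > 0.9 and d.max() < 1.05
    # planar template: no self-crossing signal
    assert abs(writhe(DiscreteCurve(conf.positions, True))) < 1e-9


@pytest.mark.parametrize("n,ns,ring,diameter", [
    (200, 10, True, 18.0),
    (100, 40, False, 30.0),
    (60, 4, True, 8.0),
])
def test_helical_template_writhe_sign(n, ns, ring, diameter):
    """Left-handed initial states have Wr < 0, right-handed Wr > 0, and the
    magnitude sits in the 1-2 band of the helically organized states."""
    topo = build_bottlebrush(n, ns, ring)
    cyl = Cylinder(diameter, None)
    wrs = {}
    for hand in ("left", "right"):
        conf = initial_conformation(topo, cyl, hand, seed=5)
        bb = conf.positions[topo.backbone_indices]
        rho = np.hypot(bb[:, 0], bb[:, 1])
        assert rho.max() < cyl.radius - 1.0 + 1e-9
        wrs[hand] = writhe(DiscreteCurve(bb, closed=ring))
        # sidechains collapsed onto anchors
        for i in (0, n // 2):
            side = conf.positions[topo.sidechain_beads(i)]
            assert np.linalg.norm(side - bb[i], axis=1).max() < 0.25
    assert wrs["left"] < 0 < wrs["right"]
    assert 0.5 < abs(wrs["left"]) < 2.5
    assert wrs["left"] == pytest.approx(-wrs["right"], abs=1e-9)


def test_left_right_are_exact_mirror_images():
    topo = build_bottlebrush(40, 3, False)
    cyl = Cylinder(10.0, None)
    left = initial_conformation(topo, cyl, "left", seed=7)
    right = initial_conformation(topo, cyl, "right", seed=7)
    mirrored = right.positions.copy()
    mirrored[:, 1] = -mirrored[:, 1]
    assert np.array_equal(left.positions, mirrored)


def test_template_too_large_raises_geometry_error():
    topo = build_bottlebrush(20, 2, False)
    with pytest.raises(GeometryError) as exc:
        initial_conformation(topo, Cylinder(2.0, None), "left")
    assert exc.value.dimension == "diameter"


def test_cylinder_validation():
    with pytest.raises(GeometryError):
        Cylinder(-1.0)
    with pytest.raises(GeometryError):
        Cylinder(4.0, -2.0)
    open_cyl = Cylinder(4.0, None)
    assert not open_cyl.closed
    with pytest.raises(GeometryError):
        open_cyl.piston_positions


def test_conformation_validate_rejects_overstretched_bond():
    topo = build_semiflexible(3, False, 0.0)
    pos = np.array([[0.0, 0, 0], [0, 0, 1.6], [0, 0, 2.6]])
    with pytest.raises(ValueError):
        Conformation(pos, np.zeros((3, 3))).validate(topo)
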
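"""Potentials and forces for the confined bead-spring model.

The model is the standard Kremer-Grest chain: FENE bonds between adjacent
beads, fully repulsive WCA excluded volume between *all* bead pairs
(bonded neighbours included, which puts the mechanical bond minimum near
0.97 sigma), an optional harmonic bending term k_b (theta - pi)^2 on
backbone angle triples, and a soft overlap-removal potential
A [1 + cos(pi r / r_c)] used only while inflating collapsed initial states.

Confinement is a smooth cylindrical wall plus two flat pistons: each surface
repels beads through the same WCA form evaluated on the bead-to-surface
distance, so a bead can approach but never cross a surface.  This realizes
a wall "made of beads of size sigma" without corrugation.

Scalar energy functions here are plain NumPy (vectorized over r) and serve
as the reference for the numba force kernels, which are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from ._kernels import WCA_CUT
from .errors import BondOverstretchError, EscapedBeadError, OverlapError

__all__ = [
    "ForceFieldParams", "fene_energy", "wca_energy", "bend_energy",
    "soft_energy", "wall_energy", "total_forces", "WCA_CUT",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """All potential constants, in reduced units (epsilon, sigma).

    fene_k is an energy per length squared; the conventional Kremer-Grest
    value 30 eps/sigma^2 together with fene_r0 = 1.5 sigma keeps bonds short
    enough that chains cannot cross each other.
    """

    fene_k: float = 30.0
    fene_r0: float = 1.5
    wca_eps: float = 1.0
    wca_sigma: float = 1.0
    bend_kb: float = 0.0
    soft_a: float = 0.0
    soft_rc: float = WCA_CUT
    temperature: float = 1.0

    def __post_init__(self):
        if self.fene_r0 <= WCA_CUT * self.wca_sigma:
            raise ValueError(
                "fene_r0 must exceed 2^(1/6) wca_sigma for a bond minimum "
                f"to exist (got r0={self.fene_r0}, sigma={self.wca_sigma})")

    def with_(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)


def fene_energy(r, params: ForceFieldParams):
    """FENE bond energy -(1/2) k r0^2 ln[1 - (r/r0)^2]; diverges at r0."""
    r = np.asarray(r, dtype=float)
    r0 = params.fene_r0
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(r >= r0):
        raise BondOverstretchError(
            f"bond length {float(np.max(r)):.6g} >= r0 = {r0}")
    out = -0.5 * params.fene_k * r0 ** 2 * np.log1p(-((r / r0) ** 2))
    return out if out.ndim else float(out)


def wca_energy(r, params: ForceFieldParams):
    """WCA energy: truncated-shifted LJ, exactly zero beyond 2^(1/6) sigma."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise OverlapError("bead pair at zero separation")
    sig, eps = params.wca_sigma, params.wca_eps
    sr6 = (sig / r) ** 6
    out = np.where(r < WCA_CUT * sig,
                   4.0 * eps * (sr6 ** 2 - sr6 + 0.25), 0.0)
    return out if out.ndim else float(out)


def bend_energy(theta, params: ForceFieldParams):
    """Harmonic bending k_b (theta - pi)^2; theta is the interior angle at
    the middle bead, pi for a locally straight chain."""
    theta = np.asarray(theta, dtype=float)
    out = params.bend_kb * (theta - np.pi) ** 2
    return out if out.ndim else float(out)


def soft_energy(r, params: ForceFieldParams):
    """Soft overlap-removal potential A [1 + cos(pi r / r_c)], zero beyond r_c."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be non-negative")
    rc = params.soft_rc
    out = np.where(r < rc, params.soft_a * (1.0 + np.cos(np.pi * r / rc)), 0.0)
    return out if out.ndim else float(out)


def wall_energy(position, cylinder, params: ForceFieldParams) -> float:
    """Confinement energy of one bead: WCA on the distance to the cylindrical
    surface of radius D/2 and, for a closed cylinder, to each piston plane."""
    x, y, z = np.asarray(position, dtype=float)
    rho = float(np.hypot(x, y))
    d_wall = cylinder.radius - rho
    if d_wall <= 0:
        raise EscapedBeadError(
            f"bead at radial distance {rho:.4g} >= radius {cylinder.radius:.4g}")
    e = wca_energy(d_wall, params)
    if cylinder.closed:
        z_lo, z_hi = cylinder.piston_positions
        for d in (z - z_lo, z_hi - z):
            if d <= 0:
                raise EscapedBeadError(f"bead at or beyond piston (z={z:.4g})")
            e += wca_energy(d, params)
    return float(e)


def total_forces(conformation, topology, cylinder, params: ForceFieldParams,
                 use_soft: bool = False):
    """Exact forces (negative energy gradient) and total potential energy.

    `cylinder` may be None for free space.  Pair sums are evaluated over all
    bead pairs; this single-shot path does not use the neighbour list and is
    meant for validation, diagnostics and initial-state checks.
    """
    pos = np.ascontiguousarray(conformation.positions, dtype=float)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    cap = n * (n - 1) // 2 + 1
    pairs = np.empty((cap, 2), np.int64)
    npairs = _kernels._build_pairs(pos, 1e30, pairs)
    has_wall = 0
    has_pistons = 0
    radius = 0.0
    z_lo = z_hi = 0.0
    if cylinder is not None:
        has_wall = 1
        radius = cylinder.radius
        if cylinder.closed:
            has_pistons = 1
            z_lo, z_hi = cylinder.piston_positions
    angles = topology.angles if topology.angles.size else np.empty((0, 3), np.int64)
    energy, status, bad = _kernels._compute_forces(
        pos, f, topology.bonds, params.fene_k, params.fene_r0,
        angles, topology.bend_kb, params.wca_eps, params.wca_sigma,
        1 if use_soft else 0, params.soft_a, params.soft_rc,
        has_wall, radius, has_pistons, z_lo, z_hi, pairs, npairs)
    if status == 1:
        raise BondOverstretchError("FENE bond at or beyond r0", index=bad,
                                   frame=pos)
    if status == 2:
        raise OverlapError("bead pair at zero separation", index=bad, frame=pos)
    if status == 4:
        raise EscapedBeadError("bead at or beyond a confining surface",
                               index=bad, frame=pos)
    return f, float(energy)
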
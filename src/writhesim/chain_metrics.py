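"""Chain observables: persistence length, extension, volume fraction.

The bending constant of the semiflexible model maps to a persistence length
through l_p = 2 k_b <b> / kBT, with <b> ~= 0.97 sigma the mean FENE+WCA bond
length.  For bottle brushes (no bending term) the effective stiffness is
measured instead by the bond-projection estimator: the ensemble average of
the backbone end-to-end vector projected onto the k-th unit bond vector,
maximized over k.  Note that for an ideal worm-like chain this projection,
taken at an interior bond, sums orientational correlations towards *both*
chain ends and therefore reads about twice the tangent-correlation
persistence length; it is reported as defined, without rescaling.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import AnalysisError, NotApplicableError

__all__ = [
    "kb_from_lp", "lp_from_kb", "persistence_projection", "extension",
    "volume_fraction", "mean_bond_length",
]


def kb_from_lp(lp: float, mean_bond: float = 0.97, kbt: float = 1.0) -> float:
    """Bending constant k_b = l_p kBT / (2 <b>) for U = k_b (theta - pi)^2."""
    if lp < 0:
        raise ValueError("persistence length must be >= 0")
    if mean_bond <= 0:
        raise ValueError("mean bond length must be positive")
    return lp * kbt / (2.0 * mean_bond)


def lp_from_kb(kb: float, mean_bond: float = 0.97, kbt: float = 1.0) -> float:
    """Inverse of :func:`kb_from_lp`: l_p = 2 k_b <b> / kBT."""
    if mean_bond <= 0:
        raise ValueError("mean bond length must be positive")
    return 2.0 * kb * mean_bond / kbt


def _as_traj_list(trajectory):
    return trajectory if isinstance(trajectory, (list, tuple)) else [trajectory]


def persistence_projection(trajectory, topology, return_profile: bool = False):
    """Persistence length from the max of <R_ee . b_hat_k> over bonds k.

    The projection is averaged over all frames (and replicas, when a list of
    trajectories is given) first; the maximum over k is taken on the averaged
    profile.  Only defined for a linear backbone.
    """
    if topology.ring:
        raise NotApplicableError(
            "end-to-end projection estimator is undefined for a ring backbone")
    bb = topology.backbone_indices
    acc = None
    n_frames = 0
    for traj in _as_traj_list(trajectory):
        pos = traj.positions[:, bb, :]        # (F, N, 3)
        bonds = np.diff(pos, axis=1)          # (F, N-1, 3)
        bhat = bonds / np.linalg.norm(bonds, axis=2, keepdims=True)
        ree = pos[:, -1, :] - pos[:, 0, :]    # (F, 3)
        proj = np.einsum("fkd,fd->fk", bhat, ree)
        acc = proj.sum(axis=0) if acc is None else acc + proj.sum(axis=0)
        n_frames += pos.shape[0]
    if n_frames == 0:
        raise AnalysisError("no frames to average over")
    profile = acc / n_frames
    lp = float(profile.max())
    return (lp, profile) if return_profile else lp


def extension(trajectory) -> float:
    """Mean longitudinal span max(z) - min(z) over all beads and frames.

    Intended for open-cylinder (L = infinity) ensembles where it estimates
    the equilibrium length R_par; on confined ensembles it returns the
    confined span (with a warning)."""
    trajs = _as_traj_list(trajectory)
    closed = any(t.metadata.get("cylinder_length") not in (None, "open")
                 for t in trajs)
    if closed:
        warnings.warn("extension() on a closed-cylinder ensemble returns the "
                      "confined span, not the equilibrium R_par", stacklevel=2)
    spans = []
    for t in trajs:
        z = t.positions[:, :, 2]
        spans.append(z.max(axis=1) - z.min(axis=1))
    return float(np.concatenate(spans).mean())


def volume_fraction(topology, cylinder, sigma: float = 1.0) -> float:
    """Monomer volume fraction phi = n_beads (pi/6) sigma^3 / (pi (D/2)^2 L).

    Each bead is counted as a sphere of diameter sigma.  Requires a closed
    cylinder (phi -> 0 as L -> infinity)."""
    if not cylinder.closed:
        raise AnalysisError("volume fraction undefined for an open cylinder")
    v_beads = topology.n_beads * (np.pi / 6.0) * sigma ** 3
    v_cyl = np.pi * cylinder.radius ** 2 * cylinder.length
    return float(v_beads / v_cyl)


def mean_bond_length(trajectory, topology) -> float:
    """Time-averaged bond length over all bonds and frames."""
    total = 0.0
    count = 0
    for traj in _as_traj_list(trajectory):
        d = (traj.positions[:, topology.bonds[:, 0], :]
             - traj.positions[:, topology.bonds[:, 1], :])
        blen = np.linalg.norm(d, axis=2)
        total += blen.sum()
        count += blen.size
    if count == 0:
        raise AnalysisError("no frames to average over")
    return float(total / count)
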
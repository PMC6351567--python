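"""Velocity-Verlet Langevin dynamics in reduced units.

Time is measured in tau = sigma sqrt(m / eps); the default time step is
0.005 tau and the thermostat damping gamma = 1 / tau, holding T = 1 eps/kB.
The friction and Gaussian random forces satisfy fluctuation-dissipation
(noise variance 2 gamma m kBT / dt per component per step); gamma = 0
recovers plain NVE velocity Verlet.  Trajectories are bit-reproducible for
a fixed seed on a given platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import (AnalysisError, BondOverstretchError, EscapedBeadError,
                     NumericalBlowupError, OverlapError, SimulationError,
                     UndefinedACFError)
from .model_builder import Conformation, Trajectory

__all__ = ["IntegratorParams", "step", "autocorrelation_time"]


@dataclass(frozen=True)
class IntegratorParams:
    """Integrator settings; tau = sigma sqrt(m/eps) is the time unit."""

    dt: float = 0.005
    gamma: float = 1.0
    temperature: float = 1.0
    mass: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0 (0 = NVE)")


_STATUS_ERRORS = {
    1: (BondOverstretchError, "FENE bond reached r0"),
    2: (OverlapError, "bead pair at zero separation"),
    3: (NumericalBlowupError, "non-finite energy detected"),
    4: (EscapedBeadError, "bead escaped through a confining surface"),
    5: (SimulationError, "neighbour-list capacity exceeded"),
}


def step(conformation: Conformation, topology, cylinder, ff_params,
         int_params: IntegratorParams, n_steps: int,
         sample_stride: int = 0, use_soft: bool = False,
         soft_ramp: tuple[float, float] | None = None,
         pistons: tuple[float, float] | None = None,
         piston_speed: float = 0.0, target_length: float | None = None):
    """Advance the system n_steps; return (conformation, trajectory).

    The input conformation is not modified.  Frames (positions, velocities,
    potential and kinetic energy) are recorded every ``sample_stride`` steps
    (0 = none).  ``cylinder`` may be None (free space).  Piston positions
    default to the cylinder's; during compression both pistons move
    symmetrically inwards at ``piston_speed`` until their gap reaches
    ``target_length``, then stop.

    On bond overstretch, bead escape or numerical blowup the corresponding
    SimulationError is raised carrying the failing step index and the last
    valid sampled frame.
    """
    pos = conformation.positions.copy()
    vel = conformation.velocities.copy()
    n = pos.shape[0]

    has_wall = 0
    radius = 0.0
    has_pistons = 0
    z_lo = z_hi = 0.0
    if cylinder is not None:
        has_wall = 1
        radius = cylinder.radius
        if pistons is not None:
            has_pistons = 1
            z_lo, z_hi = pistons
        elif cylinder.closed:
            has_pistons = 1
            z_lo, z_hi = cylinder.piston_positions
    target_gap = float(target_length) if target_length is not None else 0.0
    if piston_speed > 0.0 and not has_pistons:
        raise ValueError("piston compression requires pistons")

    a0, a1 = soft_ramp if soft_ramp is not None else (ff_params.soft_a,
                                                      ff_params.soft_a)
    n_samples_max = n_steps // sample_stride if sample_stride > 0 else 0
    out_pos = np.empty((max(n_samples_max, 1), n, 3))
    out_vel = np.empty((max(n_samples_max, 1), n, 3))
    out_times = np.empty(max(n_samples_max, 1))
    out_energy = np.empty((max(n_samples_max, 1), 2))
    angles = topology.angles if topology.angles.size else np.empty((0, 3), np.int64)

    status, fail_step, nsample, z_lo_f, z_hi_f, n_rebuilds = _kernels._run(
        pos, vel, topology.bonds, angles, topology.bend_kb,
        ff_params.fene_k, ff_params.fene_r0, ff_params.wca_eps,
        ff_params.wca_sigma, 1 if use_soft else 0, a0, a1, ff_params.soft_rc,
        has_wall, radius, has_pistons, z_lo, z_hi,
        piston_speed, target_gap,
        int_params.dt, int_params.gamma, int_params.temperature,
        int_params.mass, int_params.seed, int(n_steps),
        int(sample_stride) if sample_stride else 0,
        out_pos, out_vel, out_times, out_energy, conformation.time)

    traj = Trajectory(
        positions=out_pos[:nsample].copy(),
        times=out_times[:nsample].copy(),
        velocities=out_vel[:nsample].copy(),
        metadata={
            "energies": out_energy[:nsample].copy(),
            "pistons": (z_lo_f, z_hi_f) if has_pistons else None,
            "n_rebuilds": int(n_rebuilds),
            "seed": int_params.seed,
            "dt": int_params.dt,
            "sample_stride": int(sample_stride),
        })
    if status != 0:
        exc, msg = _STATUS_ERRORS[status]
        last = traj.positions[-1] if nsample else conformation.positions
        raise exc(f"{msg} at step {fail_step}", step=fail_step, frame=last)

    new_conf = Conformation(pos, vel,
                            time=conformation.time + n_steps * int_params.dt)
    return new_conf, traj


def autocorrelation_time(series) -> float:
    """Integrated autocorrelation time of a scalar series.

    Defined as 1/2 + sum of the normalized autocorrelation function up to
    (excluding) its first zero crossing, in units of the sampling interval;
    an AR(1) process with coefficient a has tau_int -> (1+a)/(1-a)/2, and
    white noise gives 1/2.  Used to validate that production runs are much
    longer than the relaxation time of the measured observable.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise AnalysisError("series must be one-dimensional")
    if x.size < 50:
        raise AnalysisError(
            f"autocorrelation time needs >= 50 samples (got {x.size})")
    mean = x.mean()
    x = x - mean
    var = np.dot(x, x) / x.size
    if var <= 1e-24 * (1.0 + mean * mean):
        raise UndefinedACFError("autocorrelation of a constant series")
    n = x.size
    # FFT autocovariance (biased normalization)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n] / n
    rho = acov / acov[0]
    crossings = np.flatnonzero(rho[1:] <= 0.0)
    kmax = crossings[0] + 1 if crossings.size else n
    return float(0.5 + rho[1:kmax].sum())
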
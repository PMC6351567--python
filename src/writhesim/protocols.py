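"""Staged simulation protocols and sub-ensemble (handedness) sampling.

A run proceeds through fixed stages:

* semiflexible:  build -> cap -> compress -> equilibrate -> produce
* bottle brush:  build (collapsed sidechains, helical backbone)
                 -> inflate (soft potential ramp) -> switch to WCA
                 -> cap -> compress -> equilibrate -> produce

Compression moves both pistons symmetrically towards the centre at constant
speed until their gap reaches the target cylinder length.  Only production
frames are returned; stage boundaries, seeds and piston positions are
recorded in the replica manifest so a run can be reproduced bit-exactly.

Opposite helicity states of a confined bottle brush are kinetically
separated: a brush started left-handed equilibrates and is sampled within
the left-handed sub-ensemble (local equilibrium).  A persistent sign change
of the smoothed writhe during production would indicate a (rare)
handedness flip; it is detected, logged and flagged, never silently
ignored.  The population distribution is the equal-weight sum of the left
and right sub-ensemble distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import AnalysisError
from .forcefield import ForceFieldParams
from .langevin import IntegratorParams, autocorrelation_time, step
from .model_builder import Conformation, Cylinder, Trajectory, initial_conformation
from .writhe import WritheDistribution, WritheSeries, distribution, writhe_series

__all__ = [
    "ProtocolPlan", "ReplicaResult", "run_semiflexible_protocol",
    "run_brush_protocol", "pool_subensembles", "detect_flips",
]

#: moving window (samples) for the smoothed writhe sign
FLIP_WINDOW = 50
#: consecutive opposite-sign samples that count as a handedness flip
FLIP_PERSIST = 100


@dataclass(frozen=True)
class ProtocolPlan:
    """Staged schedule; defaults are the full production schedule
    (1e8 equilibration + 2e8 production steps, sampled every 1e4 steps,
    20 replicas).  Scaled-down presets override the step counts and are
    validated against the writhe autocorrelation time."""

    target_length: Optional[float] = None    # None = open cylinder
    compress_velocity: float = 1e-3          # sigma/tau, per piston
    inflate_steps: int = 50_000
    settle_steps: int = 20_000               # WCA relaxation after inflation
    equil_steps: int = 100_000_000
    prod_steps: int = 200_000_000
    sample_stride: int = 10_000
    n_replicas: int = 20
    base_seed: int = 12345
    soft_a_max: float = 60.0
    piston_margin: float = 2.0               # initial piston clearance, sigma
    integrator: IntegratorParams = field(default_factory=IntegratorParams)
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)

    def __post_init__(self):
        if self.compress_velocity <= 0:
            raise ValueError("compress_velocity must be positive")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")

    def with_(self, **kw) -> "ProtocolPlan":
        return replace(self, **kw)

    def replica_seeds(self, n: Optional[int] = None) -> np.ndarray:
        """Independent per-replica seeds derived from base_seed."""
        n = n or self.n_replicas
        ss = np.random.SeedSequence(self.base_seed)
        return (ss.generate_state(n) % (2 ** 31 - 1)).astype(np.int64)


@dataclass
class ReplicaResult:
    """Production output of one replica."""

    replica: int
    trajectory: Trajectory
    wr: WritheSeries
    manifest: dict


def detect_flips(values: np.ndarray, window: int = FLIP_WINDOW,
                 persist: int = FLIP_PERSIST) -> list[int]:
    """Indices where the moving-average writhe sign flips persistently.

    The series is smoothed over ``window`` samples; a flip is recorded when
    the smoothed sign stays opposite to the initial sign for more than
    ``persist`` consecutive samples."""
    v = np.asarray(values, float)
    if v.size < window + persist:
        return []
    kernel = np.ones(window) / window
    smooth = np.convolve(v, kernel, mode="valid")
    ref = np.sign(smooth[0])
    if ref == 0:
        return []
    flips = []
    run = 0
    for i in range(smooth.size):
        run = run + 1 if np.sign(smooth[i]) == -ref else 0
        if run == persist:
            flips.append(i - persist + 1)
            ref = -ref
            run = 0
    return flips


def _stage_seed(seed: int, stage: int) -> int:
    return int((seed * 8 + stage) % (2 ** 31 - 1))


def _piston_bracket(conf: Conformation, margin: float) -> tuple[float, float]:
    z = conf.positions[:, 2]
    return float(z.min() - margin), float(z.max() + margin)


def _compress_steps(gap0: float, target: float, speed: float,
                    dt: float) -> int:
    if gap0 <= target:
        return 0
    return int(np.ceil((gap0 - target) / (2.0 * speed) / dt))


def _finalize(replica: int, topology, traj: Trajectory, stages: dict,
              seed: int, cylinder_length, label: str) -> ReplicaResult:
    wr = writhe_series(traj, topology, "backbone", label=label)
    under_sampled = False
    tau = np.nan
    if wr.values.size >= 50 and np.std(wr.values) > 1e-12:
        tau = autocorrelation_time(wr.values)
        under_sampled = wr.values.size < 20.0 * tau
    flips = detect_flips(wr.values) if label in ("left", "right") else []
    if flips:
        warnings.warn(
            f"replica {replica}: persistent handedness flip(s) at sample(s) "
            f"{flips} during production", stacklevel=2)
    if under_sampled:
        warnings.warn(
            f"replica {replica}: production ({wr.values.size} samples) is "
            f"shorter than 20 x tau_int ({tau:.1f} samples); marked "
            "under-sampled", stacklevel=2)
    traj.metadata.update({
        "stages": stages, "replica": replica, "seed": int(seed),
        "cylinder_length": cylinder_length, "label": label,
        "wr_tau_int": float(tau), "under_sampled": bool(under_sampled),
        "flips": flips,
    })
    return ReplicaResult(replica, traj, wr, traj.metadata.copy())


def _confined_stages(conf, topology, cyl_open, diameter, plan, seed,
                     start_stage_steps):
    """cap -> compress -> equilibrate -> produce; returns (traj, stages)."""
    ip = plan.integrator
    ff = plan.forcefield
    stages = dict(start_stage_steps)
    cursor = sum(b - a for a, b in stages.values())

    if plan.target_length is None:
        conf, _ = step(conf, topology, cyl_open, ff,
                       replace(ip, seed=_stage_seed(seed, 3)), plan.equil_steps)
        stages["equilibrate"] = (cursor, cursor + plan.equil_steps)
        cursor += plan.equil_steps
        conf, traj = step(conf, topology, cyl_open, ff,
                          replace(ip, seed=_stage_seed(seed, 4)), plan.prod_steps,
                          sample_stride=plan.sample_stride)
        stages["produce"] = (cursor, cursor + plan.prod_steps)
        return traj, stages, None

    z_lo, z_hi = _piston_bracket(conf, plan.piston_margin)
    target = float(plan.target_length)
    n_comp = _compress_steps(z_hi - z_lo, target, plan.compress_velocity,
                             ip.dt)
    cyl = Cylinder(diameter, None)  # wall only; pistons passed explicitly
    if n_comp:
        conf, ctraj = step(conf, topology, cyl, ff,
                           replace(ip, seed=_stage_seed(seed, 2)), n_comp,
                           pistons=(z_lo, z_hi),
                           piston_speed=plan.compress_velocity,
                           target_length=target)
        z_lo, z_hi = ctraj.metadata["pistons"]
        stages["compress"] = (cursor, cursor + n_comp)
        cursor += n_comp
    zc = 0.5 * (z_lo + z_hi)
    pist = (zc - target / 2.0, zc + target / 2.0)
    conf, _ = step(conf, topology, cyl, ff,
                   replace(ip, seed=_stage_seed(seed, 3)), plan.equil_steps,
                   pistons=pist)
    stages["equilibrate"] = (cursor, cursor + plan.equil_steps)
    cursor += plan.equil_steps
    conf, traj = step(conf, topology, cyl, ff,
                      replace(ip, seed=_stage_seed(seed, 4)), plan.prod_steps,
                      sample_stride=plan.sample_stride, pistons=pist)
    stages["produce"] = (cursor, cursor + plan.prod_steps)
    traj.metadata["pistons"] = pist
    return traj, stages, pist


def run_semiflexible_protocol(topology, cylinder: Cylinder,
                              plan: ProtocolPlan,
                              replicas: Optional[Sequence[int]] = None
                              ) -> list[ReplicaResult]:
    """Compress a semiflexible chain between pistons, equilibrate, produce.

    ``cylinder`` provides the diameter; the target length is
    ``plan.target_length`` (None = open cylinder, no pistons).  Each replica
    starts from the straight/serpentine template with its own seed and
    returns only production frames.
    """
    if replicas is None:
        replicas = range(plan.n_replicas)
    seeds = plan.replica_seeds(max(replicas) + 1)
    cyl_open = Cylinder(cylinder.diameter, None)
    results = []
    for r in replicas:
        seed = int(seeds[r])
        conf = initial_conformation(topology, cyl_open, "none", seed=seed,
                                    temperature=plan.integrator.temperature)
        traj, stages, _ = _confined_stages(conf, topology, cyl_open,
                                           cylinder.diameter, plan, seed, {})
        length = plan.target_length if plan.target_length is not None else "open"
        results.append(_finalize(r, topology, traj, stages, seed, length,
                                 "unlabeled"))
    return results


def run_brush_protocol(topology, cylinder: Cylinder, plan: ProtocolPlan,
                       handedness: str,
                       replicas: Optional[Sequence[int]] = None
                       ) -> list[ReplicaResult]:
    """Inflate a collapsed bottle brush, switch to WCA, cap, compress,
    equilibrate and sample within the requested helicity sub-ensemble."""
    if handedness not in ("left", "right"):
        raise ValueError("brush protocol requires handedness left or right")
    if replicas is None:
        replicas = range(plan.n_replicas)
    seeds = plan.replica_seeds(max(replicas) + 1)
    cyl_open = Cylinder(cylinder.diameter, None)
    ip = plan.integrator
    ff = plan.forcefield
    results = []
    for r in replicas:
        seed = int(seeds[r])
        conf = initial_conformation(topology, cyl_open, handedness, seed=seed,
                                    temperature=ip.temperature)
        stages = {}
        cursor = 0
        # soft-potential inflation of the collapsed sidechains
        conf, _ = step(conf, topology, cyl_open, ff,
                       replace(ip, seed=_stage_seed(seed, 0)),
                       plan.inflate_steps, use_soft=True,
                       soft_ramp=(0.0, plan.soft_a_max))
        stages["inflate"] = (cursor, cursor + plan.inflate_steps)
        cursor += plan.inflate_steps
        # soft off, WCA on; brief settle before capping
        conf, _ = step(conf, topology, cyl_open, ff,
                       replace(ip, seed=_stage_seed(seed, 1)), plan.settle_steps)
        stages["settle"] = (cursor, cursor + plan.settle_steps)
        traj, stages, _ = _confined_stages(conf, topology, cyl_open,
                                           cylinder.diameter, plan, seed,
                                           stages)
        length = plan.target_length if plan.target_length is not None else "open"
        results.append(_finalize(r, topology, traj, stages, seed, length,
                                 handedness))
    return results


def pool_subensembles(left, right, binwidth: float = 0.1,
                      kbt: float = 1.0) -> WritheDistribution:
    """Population distribution: equal-weight sum of the left-handed and
    right-handed sub-ensemble distributions (a population of equal numbers
    of left- and right-handed polymers)."""
    left = list(left) if not isinstance(left, WritheSeries) else [left]
    right = list(right) if not isinstance(right, WritheSeries) else [right]
    if not left or not right:
        raise AnalysisError("both sub-ensembles must be non-empty")
    lvals = np.concatenate([s.values for s in left])
    rvals = np.concatenate([s.values for s in right])
    return distribution([lvals, rvals], binwidth=binwidth,
                        weights=[0.5, 0.5], kbt=kbt,
                        metadata={"pooled": True,
                                  "n_left": int(lvals.size),
                                  "n_right": int(rvals.size)})
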
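"""Analytic reference curves and surrogate writhe ensembles.

These fixtures exercise every analysis stage without running dynamics:
curves whose writhe is known (planar circle: 0), oracle-computable
(solenoid, figure-eight), or bounded (planar hairpin: 0), plus seeded
Gaussian-mixture surrogates for the left/right helicity sub-ensemble
statistics.

Handedness convention matches the writhe module: a right-handed helix
(advancing +z, counterclockwise viewed from +z) has Wr > 0 and its mirror
image negates Wr exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError
from .writhe import DiscreteCurve, WritheSeries

__all__ = [
    "ShapeSpec", "make_shape", "circle", "helix", "closed_solenoid",
    "hairpin", "figure_eight", "random_walk", "surrogate_wr_ensemble",
]

FAMILIES = ("circle", "helix", "closed_solenoid", "hairpin",
            "figure_eight", "random_walk")


@dataclass(frozen=True)
class ShapeSpec:
    """Declarative description of one reference curve."""

    family: str
    n_vertices: int = 64
    radius: float = 1.0
    pitch: float = 1.0
    turns: float = 2.0
    handedness: str = "right"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise AnalysisError(
                f"unknown shape family {self.family!r}; choose from {FAMILIES}")
        if self.n_vertices < 8:
            raise AnalysisError("need >= 8 vertices")
        if self.radius <= 0 or self.pitch <= 0 or self.turns <= 0:
            raise AnalysisError("geometric parameters must be positive")


def make_shape(spec: ShapeSpec) -> DiscreteCurve:
    """Build the curve described by ``spec`` (deterministic families are
    bit-reproducible; random families are reproducible per seed)."""
    builders = {
        "circle": lambda: circle(spec.radius, spec.n_vertices),
        "helix": lambda: helix(spec.radius, spec.pitch, spec.turns,
                               spec.n_vertices, spec.handedness),
        "closed_solenoid": lambda: closed_solenoid(
            spec.radius, spec.pitch, spec.turns, spec.n_vertices,
            spec.handedness),
        "hairpin": lambda: hairpin(spec.params.get("strand_length", 10.0),
                                   spec.params.get("gap", 1.0),
                                   spec.n_vertices),
        "figure_eight": lambda: figure_eight(spec.radius, spec.n_vertices,
                                             spec.handedness),
        "random_walk": lambda: random_walk(spec.n_vertices, spec.seed),
    }
    return builders[spec.family]()


def _hand_sign(handedness: str) -> int:
    if handedness not in ("left", "right"):
        raise AnalysisError(f"handedness must be left or right, "
                            f"got {handedness!r}")
    return 1 if handedness == "right" else -1


def circle(radius: float = 1.0, n: int = 64) -> DiscreteCurve:
    """Planar closed circle in the xy-plane; Wr = 0 (no self-crossings)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    v = np.stack([radius * np.cos(t), radius * np.sin(t),
                  np.zeros(n)], axis=1)
    return DiscreteCurve(v, closed=True)


def helix(radius: float = 1.0, pitch: float = 1.0, turns: float = 2.0,
          n: int = 128, handedness: str = "right") -> DiscreteCurve:
    """Open circular helix; pitch is the rise per turn."""
    s = _hand_sign(handedness)
    t = np.linspace(0.0, turns, n)
    phi = s * 2.0 * np.pi * t
    v = np.stack([radius * np.cos(phi), radius * np.sin(phi),
                  pitch * t], axis=1)
    return DiscreteCurve(v, closed=False)


def closed_solenoid(radius: float = 1.0, pitch: float = 2.0,
                    turns: float = 3.0, n: int = 600,
                    handedness: str = "right") -> DiscreteCurve:
    """Helix of an integer number of turns closed through its own axis.

    The return path runs radially inward at the top, down the cylinder
    axis, and radially out at the bottom; in the oracle projection along
    the azimuth of the end points this adds no extra crossings, so the
    construction (and hence the oracle value) is stable.  Note the closure
    through the axis threads the coil, which reverses the sign of Wr
    relative to the bare winding sense.
    """
    if abs(turns - round(turns)) > 1e-9:
        raise AnalysisError("closed solenoid needs an integer turn count")
    s = _hand_sign(handedness)
    H = pitch * turns
    n_helix = max(int(n * 0.7), 8)
    t = np.linspace(0.0, 1.0, n_helix, endpoint=False)
    phi = s * 2.0 * np.pi * turns * t
    parts = [np.stack([radius * np.cos(phi), radius * np.sin(phi),
                       H * t], axis=1)]
    m = max((n - n_helix) // 3, 2)
    parts.append(np.stack([np.linspace(radius, 0.0, m, endpoint=False),
                           np.zeros(m), np.full(m, H)], axis=1))
    parts.append(np.stack([np.zeros(m), np.zeros(m),
                           np.linspace(H, 0.0, m, endpoint=False)], axis=1))
    m2 = n - n_helix - 2 * m
    parts.append(np.stack([np.linspace(0.0, radius, m2, endpoint=False),
                           np.zeros(m2), np.zeros(m2)], axis=1))
    return DiscreteCurve(np.concatenate(parts, axis=0), closed=True)


def hairpin(strand_length: float = 10.0, gap: float = 1.0,
            n: int = 64) -> DiscreteCurve:
    """Open planar hairpin: two antiparallel strands joined by a
    semicircular turn; planar, hence Wr = 0 exactly."""
    r = gap / 2.0
    n_turn = max(n // 5, 4)
    n_strand = (n - n_turn) // 2
    p = [np.stack([np.full(n_strand, -r), np.zeros(n_strand),
                   np.linspace(-strand_length, 0.0, n_strand,
                               endpoint=False)], axis=1)]
    a = np.linspace(np.pi, 0.0, n_turn, endpoint=False)
    p.append(np.stack([r * np.cos(a), np.zeros(n_turn),
                       r * np.sin(a)], axis=1))
    n_rest = n - n_strand - n_turn
    p.append(np.stack([np.full(n_rest, r), np.zeros(n_rest),
                       np.linspace(0.0, -strand_length, n_rest)], axis=1))
    return DiscreteCurve(np.concatenate(p, axis=0), closed=False)


def figure_eight(radius: float = 1.0, n: int = 200,
                 handedness: str = "right") -> DiscreteCurve:
    """Closed curve with a single signed crossing: a lifted lemniscate.

    The two lobes cross once near the origin; the over/under order is set
    by the handedness, so |Wr| ~ 1 with the corresponding sign.
    """
    s = _hand_sign(handedness)
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    v = np.stack([radius * np.cos(t),
                  radius * np.sin(t) * np.cos(t),
                  s * 0.25 * radius * np.sin(t)], axis=1)
    return DiscreteCurve(v, closed=True)


def random_walk(n: int = 64, seed: int = 0,
                step: float = 1.0) -> DiscreteCurve:
    """Open random walk with unit-length steps (seeded)."""
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n - 1, 3))
    d *= step / np.linalg.norm(d, axis=1, keepdims=True)
    v = np.vstack([np.zeros(3), np.cumsum(d, axis=0)])
    return DiscreteCurve(v, closed=False)


def surrogate_wr_ensemble(means, stds, weights, n: int,
                          seed: int = 0) -> list[WritheSeries]:
    """Seeded Gaussian-mixture samples of Wr, one labelled series per
    component; emulates left/right helicity sub-ensembles with the stated
    sub-ensemble statistics for testing distribution and pooling logic."""
    means = np.asarray(means, float)
    stds = np.asarray(stds, float)
    weights = np.asarray(weights, float)
    if not (means.shape == stds.shape == weights.shape):
        raise AnalysisError("means, stds, weights must have equal length")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise AnalysisError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, weights)
    out = []
    for mu, sd, c in zip(means, stds, counts):
        vals = rng.normal(mu, sd, size=c)
        label = "left" if mu < 0 else ("right" if mu > 0 else "unlabeled")
        out.append(WritheSeries(vals, np.arange(c, dtype=float), label=label))
    return out
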
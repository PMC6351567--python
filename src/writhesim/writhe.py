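"""Writhe of discrete curves, writhe time series, distributions and
free-energy landscapes, and coarse-graining/decimation of curves.

The writhe Wr of a curve is the Gauss double integral of the solid angle
over all pairs of curve points, divided by 4 pi; it counts the signed
self-crossings averaged over projection directions, and its sign encodes
the handedness of helical or interwound organization.  For a polygonal
curve the integral reduces to a double sum over non-adjacent segment
pairs, each evaluated in closed form as the signed area of a spherical
quadrilateral (pairs sharing a vertex are coplanar and contribute zero).
Open chains use the same double sum with no artificial closure.

Sign convention: a right-handed open helix (advancing +z while turning
counterclockwise viewed from +z) has Wr > 0; a mirror reflection negates
Wr exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from ._kernels import _polygon_writhe
from .errors import (CurveTooShortError, DegenerateSegmentError,
                     AnalysisError, RebinRequiredError)

__all__ = [
    "DiscreteCurve", "WritheSeries", "WritheDistribution",
    "writhe", "writhe_series", "coarse_grain", "distribution",
]


@dataclass
class DiscreteCurve:
    """An ordered polygonal curve in 3-space; closed curves include the
    segment from the last vertex back to the first."""

    vertices: np.ndarray              # (n, 3)
    closed: bool = False

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise AnalysisError("vertices must be an (n, 3) array")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def mirrored(self) -> "DiscreteCurve":
        v = self.vertices.copy()
        v[:, 1] = -v[:, 1]
        return DiscreteCurve(v, self.closed)


@dataclass
class WritheSeries:
    """Per-frame writhe values of one trajectory (one sub-ensemble member)."""

    values: np.ndarray
    frame_times: np.ndarray
    label: str = "unlabeled"          # left / right / unlabeled
    curve_source: str = "backbone"    # backbone / sidechain-path

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise AnalysisError("non-finite writhe values")


@dataclass
class WritheDistribution:
    """Normalized histogram of Wr with the free energy F = -kBT ln P.

    Bins are centred on Wr = 0 so that mirror symmetry maps bins onto bins.
    The free energy is reported relative to its minimum and only on occupied
    bins (NaN elsewhere).
    """

    bin_edges: np.ndarray
    probability: np.ndarray
    free_energy: np.ndarray
    n_samples: int
    mean: float
    std: float
    metadata: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def binwidth(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def _check_curve(curve: DiscreteCurve):
    if curve.n_vertices < 4:
        raise CurveTooShortError(
            f"writhe needs >= 4 vertices (got {curve.n_vertices})")
    v = curve.vertices
    nxt = np.roll(v, -1, axis=0) if curve.closed else v[1:]
    ref = v if curve.closed else v[:-1]
    seg = np.linalg.norm(nxt - ref, axis=1)
    if np.any(seg < 1e-12):
        raise DegenerateSegmentError(
            f"coincident consecutive vertices at index {int(np.argmin(seg))}")


def writhe(curve: DiscreteCurve) -> float:
    """Writhe of a polygonal curve (signed, dimensionless)."""
    _check_curve(curve)
    return float(_polygon_writhe(curve.vertices, curve.closed))


# ----------------------------------------------------------------------------
# curve extraction from trajectories
# ----------------------------------------------------------------------------

def _frame_path(frame: np.ndarray, topology, path_spec) -> DiscreteCurve:
    if path_spec == "backbone":
        return DiscreteCurve(frame[topology.backbone_indices],
                             closed=topology.ring)
    if isinstance(path_spec, tuple) and path_spec[0] == "sidechain_block":
        m = int(path_spec[1])
        if topology.n_side_per_monomer == 0:
            raise AnalysisError("topology has no sidechains")
        order = np.concatenate([topology.sidechain_beads(i)
                                for i in range(topology.n_backbone)])
        path = frame[order]
        curve = DiscreteCurve(path, closed=topology.ring)
        return coarse_grain(curve, "average", m) if m > 1 else curve
    raise AnalysisError(f"unresolvable path spec {path_spec!r}")


def writhe_series(trajectory, topology,
                  path_spec: Union[str, tuple] = "backbone",
                  label: str = "unlabeled") -> WritheSeries:
    """Writhe of every frame along one path through the topology.

    ``path_spec`` is ``"backbone"`` (backbone beads in chain order, closed
    iff the backbone is a ring) or ``("sidechain_block", m)``: all sidechain
    beads concatenated in backbone order, each sidechain traversed root to
    tip, then every successive block of m beads replaced by its centroid
    (emulating finite tracking resolution along the side chains).
    """
    vals = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        vals[f] = writhe(_frame_path(trajectory.positions[f], topology,
                                     path_spec))
    source = "backbone" if path_spec == "backbone" else "sidechain-path"
    return WritheSeries(vals, trajectory.times.copy(), label=label,
                        curve_source=source)


# ----------------------------------------------------------------------------
# coarse-graining
# ----------------------------------------------------------------------------

def coarse_grain(curve: DiscreteCurve, mode: str, m: int) -> DiscreteCurve:
    """Reduce curve resolution: ``average`` replaces non-overlapping blocks
    of m consecutive vertices by their centroid; ``skip`` keeps every m-th
    vertex starting at index 0.  Closure is preserved."""
    if m < 1:
        raise AnalysisError("block size m must be >= 1")
    n = curve.n_vertices
    if m > 1 and m >= n / 4:
        raise CurveTooShortError(
            f"block size {m} too large for {n} vertices")
    if m == 1:
        return DiscreteCurve(curve.vertices.copy(), curve.closed)
    if mode == "average":
        n_full = n // m
        v = curve.vertices
        out = v[:n_full * m].reshape(n_full, m, 3).mean(axis=1)
        if n % m:
            warnings.warn(
                f"curve length {n} not divisible by {m}; final partial "
                "block averaged as-is", stacklevel=2)
            out = np.vstack([out, v[n_full * m:].mean(axis=0)])
        return DiscreteCurve(out, curve.closed)
    if mode == "skip":
        return DiscreteCurve(curve.vertices[::m].copy(), curve.closed)
    raise AnalysisError(f"unknown coarse-graining mode {mode!r}")


# ----------------------------------------------------------------------------
# distributions and free energies
# ----------------------------------------------------------------------------

def _gather(series, weights):
    if isinstance(series, WritheSeries):
        items = [series]
    elif isinstance(series, np.ndarray):
        items = [series] if series.ndim == 1 else list(series)
    elif isinstance(series, (list, tuple)) and series \
            and np.isscalar(series[0]):
        items = [np.asarray(series, float)]
    else:
        items = list(series)
    vals = []
    wts = []
    for i, s in enumerate(items):
        v = s.values if isinstance(s, WritheSeries) else np.asarray(s, float)
        vals.append(v)
        w = 1.0 if weights is None else weights[i]
        wts.append(np.full(v.size, w / v.size if weights is not None else 1.0))
    return np.concatenate(vals), np.concatenate(wts)


def distribution(series, binwidth: float = 0.1,
                 weights: Optional[Sequence[float]] = None,
                 kbt: float = 1.0, min_samples: int = 100,
                 metadata: Optional[dict] = None) -> WritheDistribution:
    """Normalized P(Wr) histogram, free energy F = -kBT ln P, mean and std.

    ``series`` is one WritheSeries, an iterable of them, or raw arrays.
    With ``weights``, each input series carries the stated total weight
    (used for pooling sub-ensembles with equal weights regardless of their
    sample counts); mean and std are computed with the same weights.
    Bins have width ``binwidth`` and are centred on Wr = 0.
    """
    vals, wts = _gather(series, weights)
    if vals.size == 0:
        raise AnalysisError("empty writhe sample")
    if vals.size < min_samples:
        raise AnalysisError(
            f"need >= {min_samples} samples for a distribution "
            f"(got {vals.size}); pass min_samples to override")
    kmax = int(np.floor(np.abs(vals).max() / binwidth + 0.5)) + 1
    # bin centres at k * binwidth, k = -kmax..kmax: symmetric about Wr = 0
    edges = (np.arange(-kmax, kmax + 2) - 0.5) * binwidth
    hist, _ = np.histogram(vals, bins=edges, weights=wts)
    prob = hist / hist.sum()
    with np.errstate(divide="ignore"):
        fe = np.where(prob > 0, -kbt * np.log(prob), np.nan)
    fe = fe - np.nanmin(fe)
    wsum = wts.sum()
    mean = float(np.sum(wts * vals) / wsum)
    var = float(np.sum(wts * (vals - mean) ** 2) / wsum)
    return WritheDistribution(
        bin_edges=edges, probability=prob, free_energy=fe,
        n_samples=int(vals.size), mean=mean, std=float(np.sqrt(var)),
        metadata=metadata or {})


def pool_distributions(a: WritheDistribution,
                       b: WritheDistribution) -> WritheDistribution:
    """Equal-weight sum of two already-binned distributions.

    Requires identical binning (rebin from the raw samples otherwise).
    """
    if (a.bin_edges.shape != b.bin_edges.shape
            or not np.allclose(a.bin_edges, b.bin_edges)):
        raise RebinRequiredError(
            "distributions have incompatible binning; rebuild from samples")
    prob = 0.5 * (a.probability + b.probability)
    with np.errstate(divide="ignore"):
        fe = np.where(prob > 0, -np.log(prob), np.nan)
    fe = fe - np.nanmin(fe)
    centers = 0.5 * (a.bin_edges[:-1] + a.bin_edges[1:])
    mean = float(np.sum(prob * centers))
    var = float(np.sum(prob * (centers - mean) ** 2))
    return WritheDistribution(
        bin_edges=a.bin_edges.copy(), probability=prob, free_energy=fe,
        n_samples=a.n_samples + b.n_samples, mean=mean,
        std=float(np.sqrt(var)))
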
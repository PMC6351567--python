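"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the writhe oracle is a
brute-force Gauss-Legendre quadrature of the Gauss double integral over the
polygon, the persistence-length oracle is a tangent-correlation fit, and
the freely jointed chain sampler is plain NumPy.
"""

from __future__ import annotations

import numpy as np


_GL_CACHE: dict = {}


def _gl(k):
    if k not in _GL_CACHE:
        x, w = np.polynomial.legendre.leggauss(k)
        _GL_CACHE[k] = (0.5 * (x + 1.0), 0.5 * w)
    return _GL_CACHE[k]


def _segment_gap(a0, a1, b0, b1) -> float:
    """Minimum distance between two line segments (sampled finely; only a
    refinement criterion, not part of the integral)."""
    t = np.linspace(0.0, 1.0, 17)
    pa = a0 + t[:, None] * (a1 - a0)
    pb = b0 + t[:, None] * (b1 - b0)
    d = pa[:, None, :] - pb[None, :, :]
    return float(np.sqrt(np.sum(d * d, axis=-1).min()))


def _pair_gauss(a0, a1, b0, b1, depth: int = 0) -> float:
    """Gauss integral over one segment pair; close pairs are handled by
    recursive bisection (the integral is additive under subdivision)."""
    ta = a1 - a0
    tb = b1 - b0
    la = np.linalg.norm(ta)
    lb = np.linalg.norm(tb)
    gap = _segment_gap(a0, a1, b0, b1)
    if depth < 24 and gap < 1.0 * max(la, lb):
        am = 0.5 * (a0 + a1)
        bm = 0.5 * (b0 + b1)
        return (_pair_gauss(a0, am, b0, bm, depth + 1)
                + _pair_gauss(a0, am, bm, b1, depth + 1)
                + _pair_gauss(am, a1, b0, bm, depth + 1)
                + _pair_gauss(am, a1, bm, b1, depth + 1))
    t, w = _gl(16)
    pa = a0 + t[:, None] * ta
    pb = b0 + t[:, None] * tb
    r = pb[None, :, :] - pa[:, None, :]
    r3 = np.sum(r * r, axis=-1) ** 1.5
    num = np.tensordot(r, np.cross(tb, ta), axes=([2], [0]))
    return float(np.sum((w[:, None] * w[None, :]) * num / r3))


def quadrature_writhe(vertices: np.ndarray, closed: bool) -> float:
    """Brute-force quadrature of the Gauss double integral over all
    non-adjacent segment pairs of the polygon (adaptive Gauss-Legendre)."""
    v = np.asarray(vertices, dtype=float)
    n = v.shape[0]
    nseg = n if closed else n - 1
    total = 0.0
    for i in range(nseg - 1):
        for j in range(i + 1, nseg):
            if j == i + 1 or (closed and i == 0 and j == nseg - 1):
                continue
            total += _pair_gauss(v[i], v[(i + 1) % n], v[j], v[(j + 1) % n])
    return 2.0 * total / (4.0 * np.pi)


def sample_fjc(n_bonds: int, n_chains: int, bond: float = 0.97,
               seed: int = 0) -> np.ndarray:
    """Freely jointed chains: (n_chains, n_bonds+1, 3) ideal random walks
    with fixed bond length (no excluded volume)."""
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n_chains, n_bonds, 3))
    d *= bond / np.linalg.norm(d, axis=2, keepdims=True)
    pos = np.concatenate([np.zeros((n_chains, 1, 3)), np.cumsum(d, axis=1)],
                         axis=1)
    return pos


def tangent_correlation_lp(positions: np.ndarray, max_sep: int = 12,
                           bond: float = 0.97) -> float:
    """Persistence length from an exponential fit to the mean bond-bond
    orientational correlation <b_hat_k . b_hat_{k+m}> ~ exp(-m b / lp)."""
    bonds = np.diff(positions, axis=1)
    bhat = bonds / np.linalg.norm(bonds, axis=2, keepdims=True)
    m = np.arange(1, max_sep + 1)
    corr = [np.mean(np.einsum("fkd,fkd->fk", bhat[:, :-off], bhat[:, off:]))
            for off in m]
    slope = np.polyfit(m, np.log(corr), 1)[0]
    return float(-bond / slope)


def ar1_series(coeff: float, n: int, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) process x_t = coeff * x_{t-1} + noise."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.standard_normal() / np.sqrt(1.0 - coeff ** 2)
    eps = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = coeff * x[t - 1] + eps[t]
    return x
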
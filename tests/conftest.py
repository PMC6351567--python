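import numpy as np
import pytest

from writhesim.forcefield import ForceFieldParams
from writhesim.langevin import IntegratorParams, step
from writhesim.model_builder import Conformation, build_semiflexible


def straight_chain(n: int, spacing: float = 0.97) -> Conformation:
    z = (np.arange(n) - (n - 1) / 2.0) * spacing
    pos = np.stack([np.zeros(n), np.zeros(n), z], axis=1)
    return Conformation(pos, np.zeros((n, 3)))


@pytest.fixture(scope="session")
def lp10_free_ensemble():
    """Free-space semiflexible chain, N = 100, bending set for lp = 10a:
    5e5 equilibration + 4.5e6 production steps, shared by the persistence
    estimator checks (the single most expensive fixture in the suite)."""
    topo = build_semiflexible(100, False, 10.0)
    ff = ForceFieldParams(bend_kb=topo.bend_kb)
    conf = straight_chain(100)
    conf, _ = step(conf, topo, None, ff, IntegratorParams(seed=21), 500_000)
    _, traj = step(conf, topo, None, ff, IntegratorParams(seed=22),
                   4_500_000, sample_stride=2000)
    return topo, traj
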
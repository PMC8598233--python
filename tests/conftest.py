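"""Shared simulation fixtures.

The heavier reference simulations are session-scoped so several tests (and
the acceptance suite) can share one run: the binding-site reference run with
static sites feeds both the radial-drift sign test and the drift-prediction
test, for instance.
"""

import numpy as np
import pytest

from focisim.core import Geometry, LPMParams, PBMParams, SimulationConfig
from focisim.lpm import simulate_lpm
from focisim.pbm import simulate_pbm


@pytest.fixture(scope="session")
def pbm_static_sites_traj():
    """PBM reference run with immobile sites (Db = 0), typical kinetics.

    Reduced nucleus (r_n = 0.3 μm) for fast focus/nucleoplasm exchange;
    recorded every 0.1 ms.
    """
    p = PBMParams(geometry=Geometry(0.1, 0.3), Db=0.0)
    cfg = SimulationConfig(dt=1e-6, n_steps=100_000_000, seed=11, record_every=20)
    return simulate_pbm(p, cfg, start="equilibrium")


@pytest.fixture(scope="session")
def lpm_reference_traj():
    """Droplet reference run at typical parameters, reduced nucleus."""
    p = LPMParams(geometry=Geometry(0.1, 0.3), D0=0.05, Dn=1.0, A=5.0, b=1000.0)
    cfg = SimulationConfig(dt=1e-6, n_steps=40_000_000, seed=17, record_every=100)
    return simulate_lpm(p, cfg)


@pytest.fixture(scope="session")
def free_walk_tracks():
    """Synthetic free-diffusion 2D random walks (pure numpy oracle)."""
    from focisim.trajectory import ObservedTrack

    rng = np.random.default_rng(1234)
    D, dt = 0.5, 0.02
    tracks = []
    for k in range(200):
        n = 50
        start = rng.uniform(-1.0, 1.0, size=2)
        steps = rng.normal(scale=np.sqrt(2 * D * dt), size=(n, 2))
        xy = start + np.cumsum(steps, axis=0)
        tracks.append(ObservedTrack(t=np.arange(n) * dt, xy=xy, source_id=str(k)))
    return tracks
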
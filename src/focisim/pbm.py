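"""Event-resolved simulation of the polymer-bridging (binding-site) model.

A single tracer diffuses freely at ``Dn`` among ``N`` partially absorbing
spheres of radius ``r_b`` confined to the focus.  Crossing a site surface
binds the tracer with the Robin-condition probability
``pb = κ·sqrt(π·δt/Dn)``; otherwise the tracer is reflected radially off the
site.  A bound tracer rides its site (diffusing at ``Db``) and is released
at rate ``k_off``.  Inert crowder spheres reflect but never bind.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from . import _kernels
from .core import PBMParams, SimulationConfig, absorption_probability, smoluchowski_k_plus
from .trajectory import Trajectory

__all__ = [
    "BindingSiteState",
    "init_binding_sites",
    "add_crowders",
    "advance_sites",
    "simulate_pbm",
    "simulate_pbm_bulk",
]

# full lazy-advance sync interval (steps); bounds prescan staleness
_SYNC_EVERY = 250


@dataclass
class BindingSiteState:
    """Positions and binding status of the site ensemble.

    ``absorbing`` is False for inert crowders.  ``bound_site_index`` and
    ``bound_offset`` describe a tracer rigidly attached to a site (offset in
    the site frame, |offset| = r_b at the attachment point).
    """

    centers: np.ndarray
    absorbing: np.ndarray = field(default=None)  # type: ignore[assignment]
    bound_site_index: Optional[int] = None
    bound_offset: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.absorbing is None:
            self.absorbing = np.ones(len(self.centers), dtype=bool)
        self.absorbing = np.asarray(self.absorbing, dtype=bool)
        if len(self.absorbing) != len(self.centers):
            raise ValueError("absorbing flags must match the number of centers")

    @property
    def n_sites(self) -> int:
        return int(self.absorbing.sum())


def _uniform_ball(rng: np.random.Generator, n: int, R: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = R * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def init_binding_sites(
    p: PBMParams, seed: Union[int, np.random.Generator]
) -> BindingSiteState:
    """Draw ``N = round((4/3)π·ρ·r_f³)`` site centres uniformly in the focus.

    Sites are non-interacting and may overlap.  Crowders declared through
    ``p.crowder_count`` are appended by :func:`add_crowders`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = p.n_sites
    if n < 1:
        raise ValueError(f"binding-site density rho={p.rho} gives N={n} sites")
    state = BindingSiteState(centers=_uniform_ball(rng, n, p.geometry.r_f))
    if p.crowder_count > 0:
        state = add_crowders(state, p, p.crowder_count, rng)
    return state


def add_crowders(
    state: BindingSiteState, p: PBMParams, count: int, rng: np.random.Generator
) -> BindingSiteState:
    """Append ``count`` inert spheres of radius r_b, uniform in the focus.

    Crowders reflect the tracer (binding probability 0) and diffuse at the
    same ``Db`` as the binding sites."""
    if count < 0:
        raise ValueError("crowder count must be >= 0")
    if count == 0:
        return state
    extra = _uniform_ball(rng, count, p.geometry.r_f)
    return BindingSiteState(
        centers=np.vstack([state.centers, extra]),
        absorbing=np.concatenate([state.absorbing, np.zeros(count, dtype=bool)]),
        bound_site_index=state.bound_site_index,
        bound_offset=state.bound_offset,
    )


def advance_sites(
    state: BindingSiteState, p: PBMParams, dt: float, rng: np.random.Generator
) -> BindingSiteState:
    """One diffusive step of every site: isotropic Gaussian of per-axis
    variance 2·Db·dt, reflected radially at the focus boundary.

    A bound tracer inherits its site's displacement exactly (the returned
    state carries the same attachment)."""
    if p.Db == 0.0 or dt == 0.0:
        return replace(state, centers=state.centers.copy())
    out = state.centers + rng.normal(
        scale=np.sqrt(2.0 * p.Db * dt), size=state.centers.shape
    )
    r = np.linalg.norm(out, axis=1)
    rf = p.geometry.r_f
    bad = r > rf
    while np.any(bad):
        scale = (2.0 * rf - r[bad]) / r[bad]
        out[bad] *= scale[:, None]
        r = np.linalg.norm(out, axis=1)
        bad = r > rf
    return replace(state, centers=out)


def _pbm_equilibrium_start(p: PBMParams, rng: np.random.Generator) -> np.ndarray:
    """Sample a start position from the mean-field equilibrium density
    (enhancement 1 + ρ/Kd inside the focus, uniform outside)."""
    k_plus = smoluchowski_k_plus(p.Dn, p.r_b, p.kappa)
    w_in = 1.0 + p.rho * k_plus / p.k_off
    vf = p.geometry.focus_volume
    vn = p.geometry.nucleus_volume
    p_in = w_in * vf / (w_in * vf + (vn - vf))
    if rng.random() < p_in:
        return _uniform_ball(rng, 1, p.geometry.r_f)[0]
    while True:
        x = _uniform_ball(rng, 1, p.geometry.r_n)[0]
        if np.linalg.norm(x) > p.geometry.r_f:
            return x


def _run(
    p: PBMParams,
    cfg: SimulationConfig,
    x0: np.ndarray,
    state: BindingSiteState,
    periodic: bool,
    box: float,
) -> Trajectory:
    cfg.validate_pbm_stability(p)
    pb = absorption_probability(p.kappa, cfg.dt, p.Dn)
    n_rec = cfg.n_steps // cfg.record_every + 1
    out_pos = np.empty((n_rec, 3))
    out_bound = np.zeros(n_rec, dtype=np.uint8)
    kernel_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % 2**31)
    centers = np.ascontiguousarray(state.centers, dtype=np.float64)
    absorbing = np.ascontiguousarray(state.absorbing, dtype=np.uint8)
    _kernels.pbm_run(
        kernel_seed,
        cfg.n_steps,
        cfg.record_every,
        cfg.dt,
        float(x0[0]),
        float(x0[1]),
        float(x0[2]),
        centers,
        absorbing,
        p.Dn,
        p.Db,
        p.r_b,
        pb,
        p.k_off * cfg.dt,
        p.geometry.r_f,
        p.geometry.r_n,
        1 if periodic else 0,
        box,
        _SYNC_EVERY,
        0.0,
        out_pos,
        out_bound,
    )
    t = np.arange(n_rec) * cfg.dt * cfg.record_every
    return Trajectory(t=t, pos=out_pos, bound=out_bound, params=p, seed=cfg.seed)


def simulate_pbm(
    p: PBMParams,
    cfg: SimulationConfig,
    start: Union[str, np.ndarray] = "equilibrium",
    state: Optional[BindingSiteState] = None,
) -> Trajectory:
    """Simulate one tracer in the binding-site model (confined focus).

    Sites are re-drawn from the given seed unless an explicit ``state`` is
    passed (fixed-ensemble mode).  ``start`` is a 3D position or one of
    ``"equilibrium"`` (mean-field spatial law, unbound), ``"uniform"`` or
    ``"center"``.  The returned trajectory carries the ground-truth per-frame
    ``bound`` flag.
    """
    rng = np.random.default_rng(cfg.seed)
    if state is None:
        if p.n_sites >= 1:
            state = init_binding_sites(p, rng)
        else:
            state = BindingSiteState(
                centers=np.empty((0, 3)), absorbing=np.empty(0, dtype=bool)
            )
    if isinstance(start, str):
        if start == "equilibrium":
            x0 = (
                _pbm_equilibrium_start(p, rng)
                if p.n_sites >= 1
                else _uniform_ball(rng, 1, p.geometry.r_n)[0]
            )
        elif start == "uniform":
            x0 = _uniform_ball(rng, 1, p.geometry.r_n)[0]
        elif start == "center":
            x0 = np.zeros(3)
        else:
            raise ValueError(f"unknown start rule {start!r}")
    else:
        x0 = np.asarray(start, dtype=float)
        if np.linalg.norm(x0) > p.geometry.r_n:
            raise ValueError("start position lies outside the nucleus")
    return _run(p, cfg, x0, state, periodic=False, box=0.0)


def simulate_pbm_bulk(
    p: PBMParams, cfg: SimulationConfig, box_size: float
) -> Trajectory:
    """Simulate the PBM in an effectively infinite focus: a periodic cubic
    box filled with binding sites at density ρ (isolates bulk statistics
    from focus-boundary effects).

    The tracer coordinate is returned unwrapped; distances to sites use the
    minimum-image convention."""
    if box_size < 10.0 * p.r_b:
        raise ValueError(f"box_size must be >= 10·r_b = {10 * p.r_b}")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(p.rho * box_size**3))
    centers = rng.random((n, 3)) * box_size
    state = BindingSiteState(centers=centers)
    x0 = np.full(3, box_size / 2.0)
    return _run(p, cfg, x0, state, periodic=True, box=box_size)
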
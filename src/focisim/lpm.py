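"""Langevin simulation of the liquid-phase (droplet) model.

The tracer obeys the overdamped Itô equation

.. math::

    d\\mathbf{r} = \\left[\\nabla D - D\\,\\nabla U\\right] dt
                   + \\sqrt{2 D(r)}\\, d\\mathbf{W},

with the sigmoidal profiles of :mod:`focisim.core` (kBT ≡ 1) and a
reflecting nucleus boundary.  Because ``D`` varies only radially, the
Milstein multiplicative-noise correction is applied along the radial
direction; an Euler–Maruyama fallback is available through
``milstein=False``.
"""

from __future__ import annotations

import warnings
from typing import Union

import numpy as np
from scipy import integrate

from . import _kernels
from .core import LPMParams, SimulationConfig, lpm_diffusivity_gradient, lpm_potential
from .trajectory import Trajectory

__all__ = [
    "simulate_lpm",
    "reflect_sphere",
    "stationary_density_lpm",
    "sample_equilibrium_radius",
]


def reflect_sphere(pos_old: np.ndarray, pos_new: np.ndarray, R: float) -> np.ndarray:
    """Radial mirror reflection at the sphere ``|pos| = R``.

    Interior points are returned unchanged; an exterior point is mapped to
    radius ``2R − |pos_new|`` along the same direction, re-reflected while
    still outside.  Angular coordinates are preserved.
    """
    pos_old = np.asarray(pos_old, dtype=float)
    pos_new = np.asarray(pos_new, dtype=float)
    if np.linalg.norm(pos_old) > R * (1 + 1e-12):
        raise ValueError("pos_old must lie inside the reflecting sphere")
    r = float(np.linalg.norm(pos_new))
    if r > 3.0 * R:
        raise ValueError(
            f"|pos_new| = {r:.3g} > 3R = {3 * R:.3g}: integration step far too large"
        )
    if r <= R:
        return pos_new.copy()
    out = pos_new.copy()
    while r > R:
        out *= (2.0 * R - r) / r
        r = abs(2.0 * R - r)
    return out


def stationary_density_lpm(p: LPMParams, r_grid: np.ndarray) -> np.ndarray:
    """Boltzmann stationary radial density p(r) = e^{−U(r)}/Z (μm⁻³).

    Normalised so that ∫ 4π r² p(r) dr = 1 over the nucleus."""
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.size == 0:
        raise ValueError("r_grid must be non-empty")
    if np.any((r_grid < 0) | (r_grid > p.geometry.r_n)):
        raise ValueError("r_grid must lie within [0, r_n]")

    def integrand(r):
        return 4.0 * np.pi * r**2 * np.exp(-lpm_potential(r, p))

    rf, rn = p.geometry.r_f, p.geometry.r_n
    Z = 0.0
    for a, b in ((0.0, rf), (rf, rn)):
        val, _ = integrate.quad(integrand, a, b, limit=200)
        Z += val
    return np.exp(-lpm_potential(r_grid, p)) / Z


def sample_equilibrium_radius(p: LPMParams, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Rejection-sample radii from the Boltzmann radial law r²·e^{−U(r)}."""
    rn = p.geometry.r_n
    # proposal: r ∝ r² (uniform in the ball); acceptance weight e^{−U+U_min}
    u_min = min(0.0, p.A)  # U ranges over [min(0, A), max(0, A)]
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        r = rn * rng.random(m) ** (1.0 / 3.0)
        w = np.exp(-(lpm_potential(r, p) - u_min))
        keep = r[rng.random(m) < w]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _resolve_start(
    start: Union[str, np.ndarray], p: LPMParams, rng: np.random.Generator
) -> np.ndarray:
    rn = p.geometry.r_n
    if isinstance(start, str):
        if start == "equilibrium":
            r = sample_equilibrium_radius(p, rng, 1)[0]
        elif start == "uniform":
            r = rn * rng.random() ** (1.0 / 3.0)
        elif start == "center":
            return np.zeros(3)
        else:
            raise ValueError(f"unknown start rule {start!r}")
        v = rng.normal(size=3)
        return r * v / np.linalg.norm(v)
    start = np.asarray(start, dtype=float)
    if start.shape != (3,):
        raise ValueError("start must be a 3-vector or a start rule")
    if np.linalg.norm(start) > rn:
        raise ValueError("start position lies outside the nucleus")
    return start


def simulate_lpm(
    p: LPMParams,
    cfg: SimulationConfig,
    start: Union[str, np.ndarray] = "equilibrium",
    milstein: bool = True,
) -> Trajectory:
    """Simulate one tracer in the droplet model.

    Parameters
    ----------
    p, cfg :
        Model parameters and integration configuration.
    start :
        Either an explicit 3D position (μm), or one of ``"equilibrium"``
        (Boltzmann radial law), ``"uniform"`` (uniform in the nucleus) or
        ``"center"``.
    milstein :
        Use the Milstein scheme (default); ``False`` falls back to
        Euler–Maruyama, which needs a ~10× smaller ``dt`` for the same
        accuracy.
    """
    if not all(np.isfinite(v) for v in (p.D0, p.Dn, p.A, p.b)):
        raise ValueError("non-finite LPM parameters")
    # stability advisory: drift per step should not exceed the boundary
    # width; inside the boundary layer the kernel substeps, so the relevant
    # step is dt/_SUBSTEPS
    max_drift = (
        lpm_diffusivity_gradient(p.geometry.r_f, p) + p.Dn * abs(p.A) * p.b / 4.0
    ) * (cfg.dt / _kernels._SUBSTEPS)
    if max_drift > 1.0 / p.b:
        warnings.warn(
            f"drift per step ({max_drift:.2g} μm) exceeds the boundary width "
            f"1/b ({1.0 / p.b:.2g} μm); consider a smaller dt",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    x0 = _resolve_start(start, p, rng)
    n_rec = cfg.n_steps // cfg.record_every + 1
    out = np.empty((n_rec, 3))
    kernel_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % 2**31)
    _kernels.lpm_run(
        kernel_seed,
        cfg.n_steps,
        cfg.record_every,
        cfg.dt,
        x0[0],
        x0[1],
        x0[2],
        p.D0,
        p.Dn,
        p.A,
        p.b,
        p.geometry.r_f,
        p.geometry.r_n,
        1 if milstein else 0,
        0.0,
        out,
    )
    t = np.arange(n_rec) * cfg.dt * cfg.record_every
    return Trajectory(t=t, pos=out, bound=None, params=p, seed=cfg.seed)
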
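"""First-passage times to a central target and concentration-sensing limits.

The target is a perfectly absorbing sphere of radius ``r0`` at the centre of
the focus; nucleus and focus are concentric.  The steady-state-flux solution
of the spherically symmetric Fokker–Planck equation gives the search time

.. math::

    \\tau_a = \\int_{r_0}^{r_n} dr\\, r^2 e^{-U(r)}
              \\int_{r_0}^{r} \\frac{dr'}{D(r')\\, r'^2} e^{U(r')},

which (swapping the integration order) equals the mean first-passage time of
a particle released at the nucleus edge ``r_n``.  With sharp profiles the
double integral has a closed form, whose large-``r_n`` minimum over the
focus radius and the associated Berg–Purcell sensing bound are also
implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Union

import numpy as np
from scipy import integrate

from . import _kernels
from .core import Geometry, LPMParams, PBMParams, SimulationConfig
from .lpm import sample_equilibrium_radius
from .pbm import init_binding_sites
from .core import absorption_probability

__all__ = [
    "SearchSpec",
    "SensingSpec",
    "mfpt_quadrature",
    "mfpt_closed_form",
    "optimal_focus_radius",
    "sensing_relative_error",
    "simulate_first_passage",
    "FirstPassageSample",
]


@dataclass(frozen=True)
class SearchSpec:
    """Geometry and droplet-style transport parameters of a target search.

    ``b = inf`` means sharp (step) profiles; finite ``b`` uses the sigmoidal
    droplet profiles."""

    r0: float
    geometry: Geometry = field(default_factory=Geometry)
    D0: float = 0.05
    Dn: float = 1.0
    A: float = 5.0
    b: float = math.inf

    def __post_init__(self) -> None:
        if not (0.0 < self.r0 < self.geometry.r_f):
            raise ValueError(
                f"need 0 < r0 < r_f, got r0={self.r0}, r_f={self.geometry.r_f}"
            )
        if self.D0 <= 0 or self.Dn <= 0 or self.b <= 0:
            raise ValueError("D0, Dn and b must be > 0")


@dataclass(frozen=True)
class SensingSpec:
    """Ligand concentration (μm⁻³) and integration time (s) for sensing."""

    c: float
    t: float
    search: SearchSpec

    def __post_init__(self) -> None:
        if self.c <= 0 or self.t <= 0:
            raise ValueError("concentration and integration time must be > 0")


def _profiles(spec: SearchSpec) -> tuple[Callable[[float], float], Callable[[float], float]]:
    rf = spec.geometry.r_f
    if math.isinf(spec.b):

        def U(r: float) -> float:
            return spec.A if r > rf else 0.0

        def D(r: float) -> float:
            return spec.Dn if r > rf else spec.D0

        return U, D

    def _s(r: float) -> float:
        arg = spec.b * (r - rf)
        if arg > 700.0:
            return 1.0
        if arg < -700.0:
            return 0.0
        return 1.0 / (1.0 + math.exp(-arg))

    def U(r: float) -> float:
        return spec.A * _s(r)

    def D(r: float) -> float:
        return spec.D0 + (spec.Dn - spec.D0) * _s(r)

    return U, D


def mfpt_quadrature(
    spec: SearchSpec,
    U: Optional[Callable[[float], float]] = None,
    D: Optional[Callable[[float], float]] = None,
) -> float:
    """Numerical double quadrature of the steady-state-flux search time.

    Profiles default to the (sharp or sigmoidal) droplet forms of ``spec``;
    user-supplied ``U(r)``, ``D(r)`` callables override them.  Adaptive
    Gauss–Kronrod panels are split at the focus boundary, so step profiles
    integrate cleanly (the open rule never evaluates the discontinuity).
    """
    if U is None or D is None:
        U_d, D_d = _profiles(spec)
        U = U or U_d
        D = D or D_d
    r0, rf, rn = spec.r0, spec.geometry.r_f, spec.geometry.r_n
    if math.isinf(spec.b):
        splits = [rf]
    else:
        w = 25.0 / spec.b
        splits = sorted({min(max(rf - w, r0), rn), rf, min(rf + w, rn)})

    def inner_integrand(rp: float) -> float:
        return math.exp(U(rp)) / (D(rp) * rp * rp)

    def inner(r: float) -> float:
        pts = [r0] + [s for s in splits if r0 < s < r] + [r]
        total = 0.0
        for a, b_ in zip(pts[:-1], pts[1:]):
            val, _ = integrate.quad(inner_integrand, a, b_, epsrel=1e-11, epsabs=0, limit=200)
            total += val
        return total

    def outer_integrand(r: float) -> float:
        return r * r * math.exp(-U(r)) * inner(r)

    pts = [r0] + [s for s in splits if r0 < s < rn] + [rn]
    total = 0.0
    for a, b_ in zip(pts[:-1], pts[1:]):
        val, _ = integrate.quad(outer_integrand, a, b_, epsrel=1e-9, epsabs=0, limit=200)
        total += val
    return total


def mfpt_closed_form(spec: SearchSpec) -> float:
    """Sharp-boundary closed form of the search time (b·r_f ≫ 1 assumed).

    Exact integral of the flux formula for step profiles; the terms are the
    in-focus search, the escape/return cycles (weighted by e^{−A}), and the
    nucleoplasmic approach to the focus."""
    r0, rf, rn = spec.r0, spec.geometry.r_f, spec.geometry.r_n
    D0, Dn, A = spec.D0, spec.Dn, spec.A
    if not (r0 < rf < rn):
        raise ValueError("requires r0 < r_f < r_n")
    return (
        (rf**3 - r0**3) / (3.0 * D0 * r0)
        + (r0**2 - rf**2) / (2.0 * D0)
        + math.exp(-A)
        * ((rn**3 - rf**3) / (3.0 * D0 * r0) + (rf**3 - rn**3) / (3.0 * D0 * rf))
        + (rn**3 - rf**3) / (3.0 * Dn * rf)
        + (rf**2 - rn**2) / (2.0 * Dn)
    )


def optimal_focus_radius(
    r0: float,
    r_n: float,
    D0: float,
    Dn: float,
    A: float,
    model: Literal["LPM", "PBM"] = "LPM",
    Db: Optional[float] = None,
) -> Optional[float]:
    """Focus radius minimising the search time in the large-nucleus limit.

    LPM: rf* = [r0·r_n³·(D0/Dn − e^{−A}) / (3·(1 − e^{−A}))]^{1/4}, which
    exists only when D0·e^{A} > Dn (equivalently D0·p_in > Dn·p_out) —
    otherwise the search time is monotone in r_f and ``None`` is returned.
    PBM: the diffusivity–concentration constraint forces
    rf* = [r0·r_n³·Db/(3·Dn)]^{1/4}; immobile sites (Db = 0) give rf* = 0,
    i.e. the focus offers no search-time benefit.
    """
    if model == "LPM":
        if D0 * math.exp(A) <= Dn:
            # condition D0·e^A > Dn violated: no interior optimum
            return None
        ea = math.exp(-A)
        return (r0 * r_n**3 * (D0 / Dn - ea) / (3.0 * (1.0 - ea))) ** 0.25
    if model == "PBM":
        if Db is None:
            raise ValueError("PBM optimal size requires Db")
        return (r0 * r_n**3 * Db / (3.0 * Dn)) ** 0.25
    raise ValueError(f"unknown model {model!r}")


def sensing_relative_error(
    spec: SensingSpec,
    form: Literal["general", "large_nucleus", "strong_potential"] = "general",
) -> float:
    """Berg–Purcell-type relative error δc/c of concentration sensing.

    ``general`` uses the quadrature search time, δc/c = sqrt(3·τa/(4π·c·r_n³·t));
    ``large_nucleus`` is the r_n→∞ limit
    δc/c = sqrt([1/(Dn·r_f) + e^{−A}/D0·(1/r0 − 1/r_f)]/(4π·c·t));
    ``strong_potential`` is the optimal-focus form
    δc/c = sqrt([p_out/(4·p_in·D0·r0) + 1/(3·Dn·r_f)]/(π·c·t)) with
    p_out/p_in = e^{−A}.  At r0 = r_f the large-nucleus form reduces to the
    classic absorbing-sphere limit 1/sqrt(4π·Dn·c·r_f·t).
    """
    s = spec.search
    c, t = spec.c, spec.t
    rf = s.geometry.r_f
    if form == "general":
        tau = mfpt_quadrature(s)
        return math.sqrt(3.0 * tau / (4.0 * math.pi * c * s.geometry.r_n**3 * t))
    if form == "large_nucleus":
        term = 1.0 / (s.Dn * rf) + math.exp(-s.A) / s.D0 * (1.0 / s.r0 - 1.0 / rf)
        return math.sqrt(term / (4.0 * math.pi * c * t))
    if form == "strong_potential":
        ratio = math.exp(-s.A)  # p_out/p_in
        term = ratio / (4.0 * s.D0 * s.r0) + 1.0 / (3.0 * s.Dn * rf)
        return math.sqrt(term / (math.pi * c * t))
    raise ValueError(f"unknown form {form!r}")


@dataclass
class FirstPassageSample:
    """Monte-Carlo first-passage times with explicit censoring.

    ``times`` are absorption times (s); ``censored[i]`` marks trajectories
    that hit the step cap without absorbing (their ``times`` entry is the
    cap time, never silently truncated)."""

    times: np.ndarray
    censored: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.times[~self.censored]))

    @property
    def sem(self) -> float:
        t = self.times[~self.censored]
        return float(np.std(t, ddof=1) / math.sqrt(len(t)))

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())


def _fpt_starts(
    spec: SearchSpec,
    model_params: Union[LPMParams, PBMParams],
    rule: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    rn = spec.geometry.r_n
    if rule == "nucleus-edge":
        r = np.full(n, rn)
    elif rule == "uniform":
        r = np.empty(n)
        filled = 0
        while filled < n:
            cand = rn * rng.random(2 * (n - filled)) ** (1.0 / 3.0)
            cand = cand[cand > spec.r0]
            take = min(len(cand), n - filled)
            r[filled : filled + take] = cand[:take]
            filled += take
    elif rule == "equilibrium-outside-target":
        if isinstance(model_params, LPMParams):
            r = np.empty(n)
            filled = 0
            while filled < n:
                cand = sample_equilibrium_radius(model_params, rng, 2 * (n - filled))
                cand = cand[cand > spec.r0]
                take = min(len(cand), n - filled)
                r[filled : filled + take] = cand[:take]
                filled += take
        else:
            raise ValueError(
                "equilibrium-outside-target start is defined here for LPM parameters"
            )
    else:
        raise ValueError(f"unknown start rule {rule!r}")
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * r[:, None]


def simulate_first_passage(
    spec: SearchSpec,
    model_params: Union[LPMParams, PBMParams],
    cfg: SimulationConfig,
    n_traj: int,
    start_rule: str = "nucleus-edge",
    max_steps: int = 1_000_000_000,
) -> FirstPassageSample:
    """Monte-Carlo first-passage times to the central absorbing target.

    The default ``"nucleus-edge"`` start matches the steady-state-flux search
    time (and hence the closed form): releasing the particle at the outer
    reflecting boundary reproduces the double-integral exactly.  In-target
    detection uses the step-endpoint test at the configured ``dt``.
    """
    rng = np.random.default_rng(cfg.seed)
    starts = _fpt_starts(spec, model_params, start_rule, n_traj, rng)
    kernel_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % 2**31)
    if isinstance(model_params, LPMParams):
        out_steps = np.empty(n_traj, dtype=np.int64)
        _kernels.lpm_fpt_batch(
            kernel_seed,
            starts,
            cfg.dt,
            model_params.D0,
            model_params.Dn,
            model_params.A,
            model_params.b,
            model_params.geometry.r_f,
            model_params.geometry.r_n,
            1,
            spec.r0,
            max_steps,
            out_steps,
        )
        censored = out_steps < 0
        times = np.where(censored, max_steps, out_steps).astype(float) * cfg.dt
        return FirstPassageSample(times=times, censored=censored)
    # PBM: one kernel run per trajectory, sites re-drawn each time
    p = model_params
    cfg.validate_pbm_stability(p)
    pb = absorption_probability(p.kappa, cfg.dt, p.Dn)
    times = np.empty(n_traj)
    censored = np.zeros(n_traj, dtype=bool)
    out_pos = np.empty((1, 3))
    out_bound = np.zeros(1, dtype=np.uint8)
    for i in range(n_traj):
        state = init_binding_sites(p, rng)
        step = _kernels.pbm_run(
            int(rng.integers(2**31)),
            max_steps,
            max_steps,
            cfg.dt,
            starts[i, 0],
            starts[i, 1],
            starts[i, 2],
            np.ascontiguousarray(state.centers),
            np.ascontiguousarray(state.absorbing, dtype=np.uint8),
            p.Dn,
            p.Db,
            p.r_b,
            pb,
            p.k_off * cfg.dt,
            p.geometry.r_f,
            p.geometry.r_n,
            0,
            0.0,
            250,
            spec.r0,
            out_pos,
            out_bound,
        )
        if step < 0:
            censored[i] = True
            times[i] = max_steps * cfg.dt
        else:
            times[i] = step * cfg.dt
    return FirstPassageSample(times=times, censored=censored)
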
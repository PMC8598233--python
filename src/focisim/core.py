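"""Parameter containers, unit conventions, and elementary closed forms.

Units used throughout the package: lengths in μm, times in s, diffusivities
in μm²/s, number densities in μm⁻³, rates in s⁻¹.  Energies are measured in
units of the thermal energy, i.e. kBT ≡ 1, so a potential step of ``A`` means
an equilibrium density enhancement of ``exp(A)`` inside the focus.

The geometry is two concentric spheres centred at the origin: the focus
(radius ``r_f``) inside the nucleus (radius ``r_n``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AVOGADRO",
    "Geometry",
    "LPMParams",
    "PBMParams",
    "SimulationConfig",
    "lpm_diffusivity",
    "lpm_potential",
    "lpm_diffusivity_gradient",
    "lpm_potential_gradient",
    "smoluchowski_k_plus",
    "absorption_probability",
    "molar_to_number_density",
    "k_off_from_kd",
]

#: Avogadro's number (mol⁻¹), used to convert molar concentrations to μm⁻³.
AVOGADRO = 6.02214076e23

#: Litres per cubic micrometre: 1 L = 10¹⁵ μm³.
_LITRE_IN_UM3 = 1e15


@dataclass(frozen=True)
class Geometry:
    """Concentric focus/nucleus geometry.

    Parameters
    ----------
    r_f : float
        Focus radius (μm).
    r_n : float
        Nucleus radius (μm).
    """

    r_f: float = 0.1
    r_n: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.r_f < self.r_n):
            raise ValueError(
                f"geometry requires 0 < r_f < r_n, got r_f={self.r_f}, r_n={self.r_n}"
            )

    @property
    def focus_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.r_f**3

    @property
    def nucleus_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.r_n**3


@dataclass(frozen=True)
class LPMParams:
    """Liquid-phase (droplet) model parameters.

    The droplet is a smooth (sigmoidal) step in both the potential ``U(r)``
    and the diffusivity ``D(r)``:

    .. math::

        D(r) = D_0 + \\frac{D_n - D_0}{1 + e^{-b(r - r_f)}}, \\qquad
        U(r) = \\frac{A}{1 + e^{-b(r - r_f)}}.

    ``U`` is low (0) inside the focus and ``A`` (kBT) outside, so an
    attractive focus has ``A > 0`` and concentrates particles by ``e^A``.
    """

    geometry: Geometry = field(default_factory=Geometry)
    D0: float = 0.05
    Dn: float = 1.0
    A: float = 5.0
    b: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.D0 <= self.Dn):
            raise ValueError(f"need 0 < D0 <= Dn, got D0={self.D0}, Dn={self.Dn}")
        if self.b <= 0.0:
            raise ValueError(f"boundary steepness b must be > 0, got {self.b}")
        if not np.isfinite(self.A):
            raise ValueError("A must be finite")


@dataclass(frozen=True)
class PBMParams:
    """Polymer-bridging (binding-site) model parameters.

    The focus is a cluster of ``N = (4/3)π·rho·r_f³`` partially absorbing
    spheres of radius ``r_b`` diffusing at ``Db`` inside the focus.  An
    unbound tracer diffuses at ``Dn`` everywhere; on crossing a site surface
    it binds with the Robin-condition probability ``κ·sqrt(π·δt/Dn)`` and,
    once bound, rides the site until release at rate ``k_off``.
    """

    geometry: Geometry = field(default_factory=Geometry)
    Dn: float = 1.0
    Db: float = 0.005
    rho: float = 4.8e4
    r_b: float = 0.01
    kappa: float = 100.0
    k_off: float = 500.0
    crowder_count: int = 0

    def __post_init__(self) -> None:
        for name in ("Dn", "r_b", "kappa", "k_off"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.rho < 0.0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.Db < 0.0:
            raise ValueError(f"Db must be >= 0, got {self.Db}")
        if self.crowder_count < 0:
            raise ValueError("crowder_count must be >= 0")
        if self.r_b >= self.geometry.r_f:
            raise ValueError(
                f"binding-site radius r_b={self.r_b} must be < focus radius "
                f"r_f={self.geometry.r_f}"
            )

    @property
    def n_sites(self) -> int:
        """Number of binding sites implied by the density: (4/3)π·ρ·r_f³."""
        return int(round(self.rho * self.geometry.focus_volume))


@dataclass(frozen=True)
class SimulationConfig:
    """Integration-step configuration shared by both simulators.

    ``record_every`` thins the output: positions are stored every
    ``record_every`` integration steps, i.e. at spacing ``dt·record_every``.
    The same seed always reproduces the identical trajectory.
    """

    dt: float = 1e-6
    n_steps: int = 1_000_000
    seed: int = 0
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    def validate_pbm_stability(self, p: PBMParams, strict: bool = True) -> None:
        """Check the stability conditions of the event-driven PBM stepping.

        The per-step absorption probability must be small and the free-flight
        rms step must be small compared to the site radius.
        """
        pb = p.kappa * math.sqrt(math.pi * self.dt / p.Dn)
        step = math.sqrt(2.0 * p.Dn * self.dt)
        koffdt = p.k_off * self.dt
        problems = []
        if pb > 0.5:
            problems.append(f"absorption probability per step pb={pb:.3g} > 0.5")
        if step > 0.5 * p.r_b:
            problems.append(
                f"rms step sqrt(2·Dn·dt)={step:.3g} μm exceeds r_b/2={0.5 * p.r_b:.3g}"
            )
        if koffdt > 0.5:
            problems.append(f"k_off·dt={koffdt:.3g} > 0.5")
        if problems and strict:
            raise ValueError("PBM stability check failed: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# Elementary closed forms
# ---------------------------------------------------------------------------


def _sigmoid(x):
    # numerically safe logistic; works on scalars and arrays
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lpm_diffusivity(r, p: LPMParams):
    """Sigmoidal diffusivity profile D(r) of the droplet model (μm²/s)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance r must be >= 0")
    s = _sigmoid(p.b * (r - p.geometry.r_f))
    out = p.D0 + (p.Dn - p.D0) * s
    return float(out) if out.ndim == 0 else out


def lpm_potential(r, p: LPMParams):
    """Sigmoidal potential profile U(r) in kBT: 0 inside the focus, A outside."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance r must be >= 0")
    s = _sigmoid(p.b * (r - p.geometry.r_f))
    out = p.A * s
    return float(out) if out.ndim == 0 else out


def lpm_diffusivity_gradient(r, p: LPMParams):
    """Analytic dD/dr for the sigmoidal profile (used by the integrator)."""
    r = np.asarray(r, dtype=float)
    s = _sigmoid(p.b * (r - p.geometry.r_f))
    out = (p.Dn - p.D0) * p.b * s * (1.0 - s)
    return float(out) if out.ndim == 0 else out


def lpm_potential_gradient(r, p: LPMParams):
    """Analytic dU/dr (kBT/μm) for the sigmoidal potential."""
    r = np.asarray(r, dtype=float)
    s = _sigmoid(p.b * (r - p.geometry.r_f))
    out = p.A * p.b * s * (1.0 - s)
    return float(out) if out.ndim == 0 else out


def smoluchowski_k_plus(Dn: float, r_b: float, kappa: float) -> float:
    """Partially absorbing Smoluchowski on-rate constant (μm³/s).

    k+ = 4π·Dn·r_b / (1 + Dn/(r_b·κ)).  ``kappa=inf`` gives the fully
    absorbing limit 4π·Dn·r_b; κ→0 gives 0.
    """
    if Dn <= 0 or r_b <= 0:
        raise ValueError("Dn and r_b must be > 0")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if math.isinf(kappa):
        return 4.0 * math.pi * Dn * r_b
    return 4.0 * math.pi * Dn * r_b / (1.0 + Dn / (r_b * kappa))


def absorption_probability(kappa: float, dt: float, Dn: float) -> float:
    """Per-step binding probability for a partially absorbing surface.

    pb = κ·sqrt(π·δt/Dn), the standard discretization of the Robin boundary
    condition Dn·∂p/∂n = κ·p for a random walk of time step δt.  The result
    is dimensionless and scales as sqrt(δt).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if dt <= 0 or Dn <= 0:
        raise ValueError("dt and Dn must be > 0")
    pb = kappa * math.sqrt(math.pi * dt / Dn)
    if pb >= 1.0:
        raise ValueError(
            f"absorption probability {pb:.3g} >= 1; decrease dt (pb scales as sqrt(dt))"
        )
    return pb


def molar_to_number_density(molar: float) -> float:
    """Convert a molar concentration (mol/L) to a number density in μm⁻³."""
    if molar < 0:
        raise ValueError("concentration must be >= 0")
    return molar * AVOGADRO / _LITRE_IN_UM3


def k_off_from_kd(kd_molar: float, Dn: float, r_b: float, kappa: float) -> float:
    """Unbinding rate k− (s⁻¹) implied by a dissociation constant Kd.

    Kd = k−/k+ with the on-rate constant from :func:`smoluchowski_k_plus`;
    Kd is given in mol/L and converted to a number density internally.
    """
    k_plus = smoluchowski_k_plus(Dn, r_b, kappa)
    return molar_to_number_density(kd_molar) * k_plus
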
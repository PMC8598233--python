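"""Track-level estimators and model-discrimination statistics.

Everything here consumes either full 3D :class:`~focisim.trajectory.Trajectory`
objects or 2D :class:`~focisim.trajectory.ObservedTrack` lists (the
measurement model produces the latter from the former) and is agnostic about
which model generated the data.  Radial quantities are binned by the radius
at the *start* of each step, in windows of ``bin_width`` (default 1 nm,
i.e. 10⁻³ μm).

The dimension convention follows the data: estimators use d = 2 on projected
tracks (jump lengths are Rayleigh-distributed under free diffusion) and
d = 3 on full trajectories (Maxwell-distributed jump lengths).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core import PBMParams, SimulationConfig
from .meanfield import EffectiveProfile, predicted_radial_drift
from .trajectory import ObservedTrack, Trajectory

__all__ = [
    "RadialProfile",
    "apply_measurement_model",
    "displacement_histogram",
    "DisplacementHistogram",
    "ks_detectability",
    "DetectabilityMap",
    "radial_diffusivity_profile",
    "radial_density_profile",
    "mean_radial_displacement",
    "maximal_positive_difference",
    "MPDResult",
    "angle_distribution",
    "AngleDistribution",
    "fit_two_population_displacements",
    "TwoPopulationFit",
    "estimate_focus_center_and_params",
    "FocusEstimate",
]

Tracks = Union[Trajectory, ObservedTrack, Sequence[Union[Trajectory, ObservedTrack]]]


@dataclass
class RadialProfile:
    """Binned radial estimates: value, standard error and count per bin.

    ``se`` is NaN where a bin holds fewer than two samples; empty bins keep
    NaN values and are never interpolated."""

    bin_edges: np.ndarray
    value: np.ndarray
    se: np.ndarray
    n: np.ndarray

    @property
    def r(self) -> np.ndarray:
        """Bin centres."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_effective_profile(self, density: "RadialProfile", Dn: float, Db: float) -> EffectiveProfile:
        """Combine a diffusivity profile (self) and a density profile into an
        effective-medium profile for drift prediction."""
        if not np.array_equal(self.bin_edges, density.bin_edges):
            raise ValueError("profiles must share bin edges")
        D = self.value
        with np.errstate(invalid="ignore", divide="ignore"):
            pu = np.clip((D - Db) / (Dn - Db), 1e-12, 1.0)
            U = np.log(pu)
        return EffectiveProfile(
            r=self.r, p_unbound=pu, D_eff=D, U_eff=U, density=density.value
        )


# ---------------------------------------------------------------------------
# Measurement model
# ---------------------------------------------------------------------------


def apply_measurement_model(
    traj: Trajectory,
    sigma: float = 0.03,
    dt_obs: float = 0.02,
    z_slab: float = 0.15,
    seed: int = 0,
) -> List[ObservedTrack]:
    """Turn a simulated 3D trajectory into noisy 2D microscopy tracks.

    Subsamples to the observation interval, keeps frames with |z| ≤ z_slab
    (the visible depth of field), splits at the resulting gaps, projects to
    (x, y) and adds i.i.d. Gaussian localization noise of SD ``sigma`` per
    axis.  ``z_slab = inf`` keeps every frame.
    """
    rec_dt = traj.dt
    if rec_dt <= 0:
        raise ValueError("trajectory must have at least two frames")
    stride_f = dt_obs / rec_dt
    stride = int(round(stride_f))
    if abs(stride_f - stride) > 1e-6 or stride < 1:
        raise ValueError(
            f"dt_obs={dt_obs} is not an integer multiple of the recorded spacing {rec_dt}"
        )
    t = traj.t[::stride]
    pos = traj.pos[::stride]
    visible = np.abs(pos[:, 2]) <= z_slab
    rng = np.random.default_rng(seed)
    tracks: List[ObservedTrack] = []
    # contiguous visible runs become separate tracks
    idx = np.flatnonzero(visible)
    if len(idx) == 0:
        return tracks
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for k, run in enumerate(np.split(idx, breaks + 1)):
        if len(run) == 0:
            continue
        xy = pos[run, :2] + (rng.normal(scale=sigma, size=(len(run), 2)) if sigma > 0 else 0.0)
        tracks.append(ObservedTrack(t=t[run], xy=np.asarray(xy), source_id=f"{traj.seed}:{k}"))
    return tracks


# ---------------------------------------------------------------------------
# Generic step extraction
# ---------------------------------------------------------------------------


def _iter_tracks(tracks: Tracks) -> List[Union[Trajectory, ObservedTrack]]:
    if isinstance(tracks, (Trajectory, ObservedTrack)):
        return [tracks]
    out = list(tracks)
    if not out:
        raise ValueError("no tracks given")
    return out


def _positions(track: Union[Trajectory, ObservedTrack]) -> np.ndarray:
    return track.pos if isinstance(track, Trajectory) else track.xy


def _steps(
    tracks: Tracks, lag: int = 1, center: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Pool (start position, displacement) pairs over all tracks.

    Returns (starts, displacements, dt_obs·lag, d)."""
    tlist = _iter_tracks(tracks)
    d = _positions(tlist[0]).shape[1]
    starts, disps = [], []
    dt = None
    for tr in tlist:
        p = _positions(tr)
        if p.shape[1] != d:
            raise ValueError("mixed 2D/3D tracks")
        if len(p) <= lag:
            continue
        if dt is None and len(tr.t) > 1:
            dt = float(tr.t[1] - tr.t[0])
        c = np.zeros(d) if center is None else np.asarray(center, dtype=float)[:d]
        starts.append(p[:-lag] - c)
        disps.append(p[lag:] - p[:-lag])
    if not starts:
        raise ValueError("tracks too short for the requested lag")
    return np.vstack(starts), np.vstack(disps), float(dt) * lag, d


def _binned(
    x: np.ndarray, y: np.ndarray, edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.digitize(x, edges) - 1
    nb = len(edges) - 1
    value = np.full(nb, np.nan)
    se = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = idx == b
        nk = int(sel.sum())
        n[b] = nk
        if nk > 0:
            value[b] = y[sel].mean()
        if nk > 1:
            se[b] = y[sel].std(ddof=1) / math.sqrt(nk)
    return value, se, n


# ---------------------------------------------------------------------------
# Displacement statistics
# ---------------------------------------------------------------------------


def _jump_cdf(x: np.ndarray, D: float, dt: float, d: int) -> np.ndarray:
    """CDF of the free-diffusion jump length |δr| in d dimensions."""
    s2 = 2.0 * D * dt  # per-axis variance
    if d == 2:
        return 1.0 - np.exp(-np.square(x) / (2.0 * s2))
    # d == 3: Maxwell speed law
    return stats.chi.cdf(x / math.sqrt(s2), df=3)


@dataclass
class DisplacementHistogram:
    """Empirical jump-size distribution with a single-diffusivity overlay."""

    displacements: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray
    D_fit: float
    ks_stat: float
    ks_p: float
    d: int
    dt: float

    def theory_density(self, x: np.ndarray) -> np.ndarray:
        s2 = 2.0 * self.D_fit * self.dt
        x = np.asarray(x, dtype=float)
        if self.d == 2:
            return x / s2 * np.exp(-np.square(x) / (2 * s2))
        return (
            math.sqrt(2.0 / math.pi) * np.square(x) / s2**1.5 * np.exp(-np.square(x) / (2 * s2))
        )


def displacement_histogram(
    tracks: Tracks, lag: int = 1, bins: int = 50
) -> DisplacementHistogram:
    """Jump-size histogram with the best-fit single-D free-diffusion curve.

    The fit is the maximum-likelihood D̂ = ⟨|δr|²⟩/(2·d·δt); the KS statistic
    compares the empirical jump lengths with the fitted free-diffusion law
    (Rayleigh-type in 2D, Maxwell-type in 3D)."""
    _, disps, dt, d = _steps(tracks, lag=lag)
    jump = np.linalg.norm(disps, axis=1)
    if len(jump) < 100:
        raise ValueError(f"need >= 100 displacements, got {len(jump)}")
    D_fit = float(np.mean(jump**2) / (2.0 * d * dt))
    ks = stats.kstest(jump, lambda x: _jump_cdf(x, D_fit, dt, d))
    edges = np.linspace(0.0, jump.max(), bins + 1)
    dens, _ = np.histogram(jump, bins=edges, density=True)
    return DisplacementHistogram(
        displacements=jump,
        bin_edges=edges,
        density=dens,
        D_fit=D_fit,
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        d=d,
        dt=dt,
    )


@dataclass
class DetectabilityMap:
    """KS detectability of binding against free diffusion, per grid point."""

    dt_obs: np.ndarray
    k_off: np.ndarray
    ks_stat: np.ndarray
    p_value: np.ndarray
    detectable: np.ndarray
    alpha: float


def ks_detectability(
    pbm: PBMParams,
    dt_obs_grid: Iterable[float],
    k_off_grid: Iterable[float],
    sigma: float = 0.0,
    n_disp: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    dt: float = 1e-6,
) -> DetectabilityMap:
    """Map where the non-Gaussian jump statistics of binding are detectable.

    For each (δt_obs, k_off) a PBM simulation is run, in-focus displacements
    are collected (optionally noise-corrupted at level ``sigma``) and tested
    against the fitted free-diffusion jump law with a two-sided KS test.
    Detection degrades as k_off·δt_obs grows (binding events are averaged
    out within a frame) and as noise blurs the small-jump peak.
    """
    from dataclasses import replace as _replace

    from .pbm import simulate_pbm

    dt_grid = np.asarray(list(dt_obs_grid), dtype=float)
    ko_grid = np.asarray(list(k_off_grid), dtype=float)
    if dt_grid.size == 0 or ko_grid.size == 0:
        raise ValueError("grids must be non-empty")
    shape = (len(dt_grid), len(ko_grid))
    ks_s = np.full(shape, np.nan)
    ks_p = np.full(shape, np.nan)
    rf = pbm.geometry.r_f
    rng = np.random.default_rng(seed)
    for j, ko in enumerate(ko_grid):
        p = _replace(pbm, k_off=float(ko))
        rec = max(int(round(dt_grid.min() / dt)), 1)
        # enough steps to harvest n_disp in-focus displacements at the largest lag
        need = int(dt_grid.max() / dt) * n_disp * 3
        cfg = SimulationConfig(
            dt=dt, n_steps=need, seed=int(rng.integers(2**31)), record_every=rec
        )
        traj = simulate_pbm(p, cfg, start="center")
        for i, dto in enumerate(dt_grid):
            lag = int(round(dto / (dt * rec)))
            pos = traj.pos[::lag] if lag > 1 else traj.pos
            xy = pos[:, :2]
            if sigma > 0:
                xy = xy + rng.normal(scale=sigma, size=xy.shape)
            r_start = np.linalg.norm(pos[:-1], axis=1)
            disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
            disp = disp[r_start < rf][:n_disp]
            if len(disp) < 50:
                continue
            D_fit = float(np.mean(disp**2) / (4.0 * dto))
            res = stats.kstest(disp, lambda x: _jump_cdf(x, D_fit, dto, 2))
            ks_s[i, j] = res.statistic
            ks_p[i, j] = res.pvalue
    return DetectabilityMap(
        dt_obs=dt_grid,
        k_off=ko_grid,
        ks_stat=ks_s,
        p_value=ks_p,
        detectable=ks_p < alpha,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Radial profiles
# ---------------------------------------------------------------------------


def _default_edges(r: np.ndarray, bin_width: float, r_max: Optional[float]) -> np.ndarray:
    hi = r_max if r_max is not None else float(r.max())
    nb = max(int(math.ceil(hi / bin_width)), 1)
    return np.arange(nb + 1) * bin_width


def radial_diffusivity_profile(
    tracks: Tracks,
    center: Optional[np.ndarray] = None,
    bin_width: float = 1e-3,
    r_max: Optional[float] = None,
    noise_sigma: float = 0.0,
) -> RadialProfile:
    """Apparent diffusivity D̃(r) = ⟨|δr|²⟩/(2·d·δt) binned by start radius.

    With ``noise_sigma`` set, the localization-noise floor 2·d·σ² is
    subtracted from the squared displacement before division (the static
    term of MSD = 2·d·D·δt + 2·d·σ²)."""
    starts, disps, dt, d = _steps(tracks, center=center)
    r = np.linalg.norm(starts, axis=1)
    y = (np.sum(disps**2, axis=1) - 2.0 * d * noise_sigma**2) / (2.0 * d * dt)
    edges = _default_edges(r, bin_width, r_max)
    value, se, n = _binned(r, y, edges)
    return RadialProfile(bin_edges=edges, value=value, se=se, n=n)


def radial_density_profile(
    tracks: Tracks,
    center: Optional[np.ndarray] = None,
    bin_width: float = 1e-3,
    r_max: Optional[float] = None,
    z_slab: Optional[float] = None,
) -> RadialProfile:
    """Stationary particle density p(r), normalised so ∫ p dV = 1.

    3D tracks use exact spherical-shell volumes.  2D projected tracks use
    annulus areas times the slab depth 2·z_slab (a local approximation valid
    when the slab is thin compared to the radial scale of the density)."""
    tlist = _iter_tracks(tracks)
    d = _positions(tlist[0]).shape[1]
    c = np.zeros(d) if center is None else np.asarray(center, dtype=float)[:d]
    r = np.concatenate([np.linalg.norm(_positions(tr) - c, axis=1) for tr in tlist])
    edges = _default_edges(r, bin_width, r_max)
    counts, _ = np.histogram(r, bins=edges)
    if d == 3:
        vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    else:
        area = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        depth = 2.0 * z_slab if z_slab else 1.0
        vol = area * depth
    total = counts.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        value = counts / (total * vol)
        se = np.sqrt(counts) / (total * vol)
    se[counts < 2] = np.nan
    return RadialProfile(bin_edges=edges, value=value, se=se, n=counts)


def mean_radial_displacement(
    tracks: Tracks,
    center: Optional[np.ndarray] = None,
    bin_width: float = 1e-3,
    r_max: Optional[float] = None,
) -> RadialProfile:
    """Mean radial displacement ⟨δr⟩(r) = ⟨r_{t+δt} − r_t⟩ by start radius."""
    starts, disps, dt, d = _steps(tracks, center=center)
    r0 = np.linalg.norm(starts, axis=1)
    r1 = np.linalg.norm(starts + disps, axis=1)
    edges = _default_edges(r0, bin_width, r_max)
    value, se, n = _binned(r0, r1 - r0, edges)
    return RadialProfile(bin_edges=edges, value=value, se=se, n=n)


# ---------------------------------------------------------------------------
# PBM rejection statistic
# ---------------------------------------------------------------------------


@dataclass
class MPDResult:
    """Maximal positive difference between observed and PBM-predicted drift.

    ``mpd`` is the largest positive excess of the observed mean radial
    displacement over the constraint-based prediction in the boundary
    window; ``se`` is its block-bootstrap standard error.  Because a maximum
    over many bins is positively biased even for pure noise, rejection is
    judged against the bootstrap null distribution of the noise maximum
    (``noise_max_mean`` ± ``noise_max_sd``)."""

    mpd: float
    se: float
    noise_max_mean: float
    noise_max_sd: float
    r: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray

    def rejects_pbm(self, n_se: float = 3.0) -> bool:
        return self.mpd > self.noise_max_mean + n_se * self.noise_max_sd


def maximal_positive_difference(
    tracks: Tracks,
    r_f: float,
    Db_assumed: float,
    Dn: Optional[float] = None,
    center: Optional[np.ndarray] = None,
    bin_width: float = 1e-3,
    n_boot: int = 60,
    block_frames: int = 500,
    seed: int = 0,
) -> MPDResult:
    """PBM-rejection statistic around the focus boundary.

    Predicts the mean radial displacement from the *measured* D̃(r) and p(r)
    profiles under the binding-site constraint, and returns the maximum of
    (observed − predicted) over r ∈ [0.5·r_f, 1.5·r_f].  In PBM-generated
    data the difference is statistical noise; droplet data with (D0, A)
    decoupled produce a positive excess — the boundary 'reflection' the
    binding-site model cannot generate.  Errors come from a moving-block
    bootstrap over contiguous step blocks.
    """
    tlist = _iter_tracks(tracks)
    starts, disps, dt, d = _steps(tlist, center=center)
    lo, hi = 0.5 * r_f, 1.5 * r_f
    edges = np.arange(0.0, hi + 5 * bin_width, bin_width)
    nb = len(edges) - 1
    rmid = 0.5 * (edges[:-1] + edges[1:])
    r0 = np.linalg.norm(starts, axis=1)
    r1 = np.linalg.norm(starts + disps, axis=1)
    d2 = np.sum(disps**2, axis=1)
    bi = np.clip(np.digitize(r0, edges) - 1, 0, nb - 1)
    if d == 3:
        vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    else:
        vol = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    win = (rmid >= lo) & (rmid <= hi)

    def _curve(sel: np.ndarray) -> np.ndarray:
        cnt = np.bincount(bi[sel], minlength=nb).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            obs = np.bincount(bi[sel], weights=(r1 - r0)[sel], minlength=nb) / cnt
            Dva = np.bincount(bi[sel], weights=d2[sel], minlength=nb) / cnt / (2 * d * dt)
            dens = cnt / max(cnt.sum(), 1) / vol
        ok = (cnt > 100) & np.isfinite(Dva) & (dens > 0) & (Dva > Db_assumed)
        if Dn is not None:
            Dn_loc = Dn
        else:
            far = ok & (rmid > 1.2 * r_f)
            Dn_loc = float(np.nansum(Dva[far] * cnt[far]) / cnt[far].sum()) if far.any() else np.nan
        if not np.isfinite(Dn_loc) or ok.sum() < 5:
            raise ValueError("insufficient boundary statistics for the MPD")
        prof = EffectiveProfile(
            r=rmid[ok],
            p_unbound=np.clip((Dva[ok] - Db_assumed) / (Dn_loc - Db_assumed), 1e-9, 1.0),
            D_eff=Dva[ok],
            U_eff=np.zeros(int(ok.sum())),
            density=dens[ok],
        )
        pred = predicted_radial_drift(prof, dt, d=d)
        out = np.full(nb, np.nan)
        out[ok] = obs[ok] - pred
        return out

    n_pairs = len(starts)
    d0 = _curve(np.ones(n_pairs, dtype=bool))
    if not np.isfinite(d0[win]).any():
        raise ValueError("no populated bins in the boundary window")
    mpd = float(np.nanmax(d0[win]))
    rng = np.random.default_rng(seed)
    block = min(block_frames, max(n_pairs // 10, 1))
    nblocks = max(n_pairs // block, 2)
    stat_boot, null_boot = [], []
    for _ in range(n_boot):
        pick = rng.integers(nblocks, size=nblocks)
        idx = (pick[:, None] * block + np.arange(block)[None, :]).ravel()
        idx = idx[idx < n_pairs]
        sel = np.zeros(n_pairs, dtype=bool)
        sel[idx] = True
        try:
            dk = _curve(sel)
        except ValueError:
            continue
        with np.errstate(invalid="ignore"):
            stat_boot.append(np.nanmax(dk[win]))
            null_boot.append(np.nanmax((dk - d0)[win]))
    se = float(np.std(stat_boot, ddof=1)) if len(stat_boot) > 2 else float("nan")
    nmean = float(np.mean(null_boot)) if null_boot else float("nan")
    nsd = float(np.std(null_boot, ddof=1)) if len(null_boot) > 2 else float("nan")
    pred_curve = np.full(nb, np.nan)
    obs_curve = np.full(nb, np.nan)
    # recompute the full curves once for reporting
    cnt = np.bincount(bi, minlength=nb).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_all = np.bincount(bi, weights=(r1 - r0), minlength=nb) / cnt
    obs_curve[:] = obs_all
    pred_curve[:] = obs_all - d0
    return MPDResult(
        mpd=mpd,
        se=se,
        noise_max_mean=nmean,
        noise_max_sd=nsd,
        r=rmid[win],
        observed=obs_curve[win],
        predicted=pred_curve[win],
    )


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------


@dataclass
class AngleDistribution:
    """Distribution of angles between consecutive displacements (degrees)."""

    bin_edges: np.ndarray
    density: np.ndarray
    n: int
    asymmetry: float  # fraction in [150°,180°] / fraction in [0°,30°]


def angle_distribution(tracks: Tracks, bins: int = 18) -> AngleDistribution:
    """Angles between consecutive displacement vectors, over [0°, 180°].

    Uniform for free diffusion in a homogeneous environment; confinement and
    obstacles enrich reversals (θ → 180°).  Zero-length displacements are
    skipped (no direction defined)."""
    tlist = _iter_tracks(tracks)
    angles = []
    for tr in tlist:
        p = _positions(tr)
        if len(p) < 3:
            continue
        v = np.diff(p, axis=0)
        a, b = v[:-1], v[1:]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        ok = (na > 0) & (nb > 0)
        cosang = np.clip(np.sum(a[ok] * b[ok], axis=1) / (na[ok] * nb[ok]), -1.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
    if not angles:
        raise ValueError("need tracks with >= 3 consecutive frames")
    ang = np.concatenate(angles)
    edges = np.linspace(0.0, 180.0, bins + 1)
    dens, _ = np.histogram(ang, bins=edges, density=True)
    rev = np.mean(ang >= 150.0)
    fwd = np.mean(ang <= 30.0)
    asym = rev / fwd if fwd > 0 else math.inf
    return AngleDistribution(bin_edges=edges, density=dens, n=len(ang), asymmetry=asym)


# ---------------------------------------------------------------------------
# Two-population mixture and focus estimation
# ---------------------------------------------------------------------------


@dataclass
class TwoPopulationFit:
    """Zero-mean two-Gaussian mixture fit of per-axis displacements."""

    D_slow: float
    D_fast: float
    weight_slow: float
    converged: bool
    degenerate: bool
    n_iter: int


def fit_two_population_displacements(
    tracks: Tracks, sigma: float = 0.0, dt_obs: Optional[float] = None
) -> TwoPopulationFit:
    """EM fit of per-axis displacements with two zero-mean Gaussians.

    The slow/fast components correspond to in-focus and nucleoplasmic steps.
    Variances are converted to diffusivities through the localization-noise
    relation var = 2·D·δt + 2·σ² per axis.  A variance ratio below 1.5 is
    flagged degenerate (one population suffices); the pooled D is then
    reported in both components.
    """
    _, disps, dt, d = _steps(tracks)
    if dt_obs is None:
        dt_obs = dt
    x = disps.ravel()
    v_all = float(np.var(x))
    v1, v2, w = 0.2 * v_all, 2.0 * v_all, 0.5
    converged = False
    it = 0
    for it in range(1, 501):
        g1 = w * np.exp(-0.5 * x**2 / v1) / math.sqrt(v1)
        g2 = (1 - w) * np.exp(-0.5 * x**2 / v2) / math.sqrt(v2)
        resp = g1 / (g1 + g2 + 1e-300)
        w_new = float(resp.mean())
        v1_new = float(np.sum(resp * x**2) / max(resp.sum(), 1e-300))
        v2_new = float(np.sum((1 - resp) * x**2) / max((1 - resp).sum(), 1e-300))
        delta = abs(v1_new - v1) / v1 + abs(v2_new - v2) / v2 + abs(w_new - w)
        v1, v2, w = v1_new, v2_new, w_new
        if delta < 1e-10:
            converged = True
            break
    if v1 > v2:
        v1, v2, w = v2, v1, 1.0 - w
    degenerate = (v2 / v1) < 1.5 or w < 0.01 or w > 0.99
    if degenerate:
        D = (v_all - 2.0 * sigma**2) / (2.0 * dt_obs)
        return TwoPopulationFit(D, D, 1.0, converged, True, it)
    D1 = (v1 - 2.0 * sigma**2) / (2.0 * dt_obs)
    D2 = (v2 - 2.0 * sigma**2) / (2.0 * dt_obs)
    return TwoPopulationFit(D1, D2, w, converged, False, it)


@dataclass
class FocusEstimate:
    center: np.ndarray
    r_f: float
    D0: float
    A: float


def estimate_focus_center_and_params(
    tracks: Tracks, bandwidth: float = 0.15, bin_width: float = 5e-3
) -> FocusEstimate:
    """Estimate the focus centre, radius, in-focus diffusivity and potential.

    Centre: mean-shift mode of the position cloud (bandwidth ~ focus scale).
    r_f: radius where the radial density falls halfway between its central
    and far plateaus.  D0: mean apparent diffusivity at r < 0.8·r_f.
    A: log ratio of the density plateaus (r < 0.8·r_f vs r > 1.5·r_f).
    Raises if no density enhancement is detected.
    """
    tlist = _iter_tracks(tracks)
    pos = np.vstack([_positions(tr) for tr in tlist])
    d = pos.shape[1]
    center = np.median(pos, axis=0)
    for _ in range(100):
        dist = np.linalg.norm(pos - center, axis=1)
        sel = dist < bandwidth
        if sel.sum() < 10:
            break
        new = pos[sel].mean(axis=0)
        if np.linalg.norm(new - center) < 1e-6:
            center = new
            break
        center = new
    dens = radial_density_profile(tlist, center=center, bin_width=bin_width)
    r = dens.r
    good = dens.n > 0

    def _plateau(sel):
        # count-weighted mean density over a radial band
        if not (good & sel).any():
            return np.nan
        s = good & sel
        return float(np.sum(dens.value[s] * dens.n[s]) / dens.n[s].sum())

    # background band well inside the sampled support (avoids partially
    # covered outer shells when the centre estimate is off)
    r_hi = float(np.quantile(np.linalg.norm(pos - center, axis=1), 0.995))
    p_c = _plateau(r < 0.05)
    p_far = _plateau((r > 0.6 * r_hi) & (r < 0.85 * r_hi))
    if not np.isfinite(p_c) or not np.isfinite(p_far) or p_c < 2.0 * p_far:
        raise ValueError("no focus: central density enhancement below 2x background")
    half = 0.5 * (p_c + p_far)
    below = good & (dens.value < half) & (r > 0.02)
    if not below.any():
        raise ValueError("no focus boundary found within the sampled range")
    r_f = float(r[below][0])
    diff = radial_diffusivity_profile(tlist, center=center, bin_width=bin_width)
    in_sel = (diff.r < 0.8 * r_f) & (diff.n > 10)
    out_sel = (dens.r > 1.5 * r_f) & (dens.r < 0.85 * r_hi) & (dens.n > 0)
    in_dens = (dens.r < 0.8 * r_f) & (dens.n > 0)
    if not in_sel.any() or not out_sel.any():
        raise ValueError("insufficient statistics inside/outside the focus")
    D0 = float(np.nansum(diff.value[in_sel] * diff.n[in_sel]) / diff.n[in_sel].sum())
    pin = float(np.nansum(dens.value[in_dens] * dens.n[in_dens]) / dens.n[in_dens].sum())
    pout = float(np.nansum(dens.value[out_sel] * dens.n[out_sel]) / dens.n[out_sel].sum())
    return FocusEstimate(center=center, r_f=r_f, D0=D0, A=float(np.log(pin / pout)))
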
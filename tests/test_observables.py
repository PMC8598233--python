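"""Estimators on synthetic and simulated tracks."""

import numpy as np
import pytest

from focisim.trajectory import ObservedTrack, Trajectory
from focisim.observables import (
    angle_distribution,
    apply_measurement_model,
    displacement_histogram,
    estimate_focus_center_and_params,
    fit_two_population_displacements,
    ks_detectability,
    maximal_positive_difference,
    mean_radial_displacement,
    radial_density_profile,
    radial_diffusivity_profile,
)


def _static_traj(n=2000, dt=0.02):
    return Trajectory(
        t=np.arange(n) * dt, pos=np.zeros((n, 3)), bound=None, params=None, seed=0
    )


def _uniform_ball_traj(n, R, seed=0, dt=0.02):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pos = v * (R * rng.random((n, 1)) ** (1 / 3))
    return Trajectory(t=np.arange(n) * dt, pos=pos, bound=None, params=None, seed=seed)


class TestMeasurementModel:
    def test_noise_free_projection(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(scale=0.05, size=(100, 3))
        tr = Trajectory(t=np.arange(100) * 0.01, pos=pos, bound=None, params=None, seed=0)
        obs = apply_measurement_model(tr, sigma=0.0, dt_obs=0.02, z_slab=np.inf)
        assert len(obs) == 1
        np.testing.assert_array_equal(obs[0].xy, pos[::2, :2])

    def test_static_particle_noise_variance(self):
        obs = apply_measurement_model(_static_traj(), sigma=0.03, dt_obs=0.02, z_slab=1.0, seed=1)
        d = np.diff(obs[0].xy, axis=0)
        # apparent per-axis displacement variance of a static emitter: 2σ²
        np.testing.assert_allclose(d.var(axis=0), 2 * 0.03**2, rtol=0.1)

    def test_slab_retention_matches_geometry(self):
        tr = _uniform_ball_traj(200_000, R=0.3, seed=2)
        obs = apply_measurement_model(tr, sigma=0.0, dt_obs=0.02, z_slab=0.15)
        kept = sum(len(o) for o in obs)
        h = 0.15 / 0.3
        expect = 1.5 * h - 0.5 * h**3  # slab ∩ ball volume fraction
        assert kept / len(tr.t) == pytest.approx(expect, rel=0.02)

    def test_gap_splitting(self):
        pos = np.zeros((6, 3))
        pos[2, 2] = 5.0  # one frame far out of the slab
        tr = Trajectory(t=np.arange(6) * 0.02, pos=pos, bound=None, params=None, seed=0)
        obs = apply_measurement_model(tr, sigma=0.0, dt_obs=0.02, z_slab=0.15)
        assert [len(o) for o in obs] == [2, 3]

    def test_incommensurate_interval_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            apply_measurement_model(_static_traj(dt=0.02), dt_obs=0.03)


class TestDisplacementHistogram:
    def test_free_diffusion_fits_rayleigh(self, free_walk_tracks):
        h = displacement_histogram(free_walk_tracks)
        assert h.d == 2
        assert h.D_fit == pytest.approx(0.5, rel=0.03)
        assert h.ks_p > 0.01

    def test_mixture_is_non_gaussian(self):
        rng = np.random.default_rng(3)
        dt = 0.02
        tracks = []
        for k in range(100):
            D = 0.02 if k % 2 else 1.0
            steps = rng.normal(scale=np.sqrt(2 * D * dt), size=(60, 2))
            tracks.append(
                ObservedTrack(t=np.arange(60) * dt, xy=np.cumsum(steps, axis=0), source_id=str(k))
            )
        h = displacement_histogram(tracks)
        assert h.ks_p < 0.01

    def test_too_few_displacements(self):
        tr = ObservedTrack(t=np.arange(5) * 0.02, xy=np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="100"):
            displacement_histogram(tr)


class TestRadialProfiles:
    def test_flat_diffusivity_for_free_walks(self, free_walk_tracks):
        prof = radial_diffusivity_profile(free_walk_tracks, bin_width=0.2)
        sel = prof.n > 200
        assert sel.sum() >= 3
        resid = np.abs(prof.value[sel] - 0.5) / prof.se[sel]
        assert np.all(resid < 3.5)

    def test_uniform_density_flat_in_volume(self):
        tr = _uniform_ball_traj(300_000, R=0.3, seed=4)
        prof = radial_density_profile(tr, bin_width=0.03)
        sel = prof.n > 500
        expect = 1.0 / (4 / 3 * np.pi * 0.3**3)
        np.testing.assert_allclose(prof.value[sel], expect, rtol=0.06)

    def test_mean_radial_displacement_free_polar_drift(self, free_walk_tracks):
        # d = 2 free diffusion: ⟨δr⟩ ≈ δt·D/r
        prof = mean_radial_displacement(free_walk_tracks, bin_width=0.2)
        sel = prof.n > 300
        expect = 0.02 * 0.5 / prof.r[sel]
        resid = np.abs(prof.value[sel] - expect) / prof.se[sel]
        assert np.all(resid < 3.5)

    def test_rotation_invariance(self, free_walk_tracks):
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = [
            ObservedTrack(t=tr.t, xy=tr.xy @ R.T, source_id=tr.source_id)
            for tr in free_walk_tracks
        ]
        a = radial_diffusivity_profile(free_walk_tracks, bin_width=0.2)
        b = radial_diffusivity_profile(rotated, bin_width=0.2)
        np.testing.assert_allclose(a.value[a.n > 0], b.value[b.n > 0], rtol=1e-9)

    def test_lpm_profile_plateaus(self, lpm_reference_traj):
        tr = lpm_reference_traj
        prof = radial_diffusivity_profile(tr, bin_width=5e-3, r_max=0.28)
        inside = (prof.r < 0.07) & (prof.n > 100)
        outside = (prof.r > 0.15) & (prof.r < 0.24) & (prof.n > 100)
        D0 = np.nanmean(prof.value[inside])
        Dn = np.nanmean(prof.value[outside])
        assert D0 == pytest.approx(0.05, rel=0.10)
        assert Dn == pytest.approx(1.0, rel=0.10)
        dens = radial_density_profile(tr, bin_width=5e-3, r_max=0.28)
        pin = np.nansum(dens.value[inside] * dens.n[inside]) / dens.n[inside].sum()
        pout = np.nansum(dens.value[outside] * dens.n[outside]) / dens.n[outside].sum()
        # one 40 s run: ~70 focus visits, so the ratio carries ~±15% noise
        assert pin / pout == pytest.approx(np.exp(5.0), rel=0.4)


class TestAngles:
    def test_free_diffusion_uniform(self, free_walk_tracks):
        ang = angle_distribution(free_walk_tracks)
        assert 0.85 < ang.asymmetry < 1.2

    def test_confined_droplet_enriches_reversals(self, lpm_reference_traj):
        obs = apply_measurement_model(
            lpm_reference_traj, sigma=0.0, dt_obs=0.02, z_slab=np.inf, seed=0
        )
        ang = angle_distribution(obs)
        assert ang.asymmetry > 1.5

    def test_needs_three_frames(self):
        tr = ObservedTrack(t=np.arange(2) * 0.02, xy=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="3 consecutive"):
            angle_distribution(tr)


class TestKSDetectability:
    def test_no_sites_never_detectable_and_monotone_in_k_off(self):
        from focisim.core import Geometry, PBMParams

        base = PBMParams(geometry=Geometry(0.1, 0.3), Db=0.0, kappa=100.0)
        null = PBMParams(geometry=Geometry(0.1, 0.3), rho=0.0)
        m_null = ks_detectability(null, [2e-3], [500.0], n_disp=800, seed=5)
        assert not m_null.detectable.any()
        m = ks_detectability(base, [2e-3], [50.0, 5000.0], n_disp=800, seed=6)
        # slow unbinding → pronounced non-Gaussianity → larger KS statistic
        assert m.ks_stat[0, 0] > m.ks_stat[0, 1]
        m_noise = ks_detectability(base, [2e-3], [50.0], sigma=0.03, n_disp=800, seed=6)
        assert m_noise.ks_stat[0, 0] < m.ks_stat[0, 0]


class TestTwoPopulationFit:
    def _mixture_tracks(self, D1, D2, w1, n, dt=0.02, seed=7):
        rng = np.random.default_rng(seed)
        xs = []
        n1 = int(n * w1)
        xs.append(rng.normal(scale=np.sqrt(2 * D1 * dt), size=(n1, 2)))
        xs.append(rng.normal(scale=np.sqrt(2 * D2 * dt), size=(n - n1, 2)))
        steps = np.vstack(xs)
        xy = np.cumsum(steps, axis=0)
        return [ObservedTrack(t=np.arange(n) * dt, xy=xy)]

    def test_recovers_two_populations(self):
        fit = fit_two_population_displacements(
            self._mixture_tracks(0.05, 1.0, 0.5, 10_000)
        )
        assert not fit.degenerate
        assert fit.D_slow == pytest.approx(0.05, rel=0.15)
        assert fit.D_fast == pytest.approx(1.0, rel=0.15)
        assert fit.weight_slow == pytest.approx(0.5, abs=0.08)

    def test_single_population_flagged_degenerate(self):
        fit = fit_two_population_displacements(
            self._mixture_tracks(0.5, 0.5, 0.5, 5_000)
        )
        assert fit.degenerate
        assert fit.D_slow == pytest.approx(0.5, rel=0.05)

    def test_noise_correction(self):
        # σ > 0 shifts the recovered D down by σ²/δt exactly
        tracks = self._mixture_tracks(0.5, 0.5, 0.5, 5_000)
        f0 = fit_two_population_displacements(tracks, sigma=0.0)
        f1 = fit_two_population_displacements(tracks, sigma=0.03)
        assert f0.D_slow - f1.D_slow == pytest.approx(0.03**2 / 0.02, rel=1e-6)


class TestFocusEstimation:
    def test_uniform_tracks_raise(self):
        tr = _uniform_ball_traj(50_000, R=0.3, seed=8)
        with pytest.raises(ValueError, match="no focus"):
            estimate_focus_center_and_params(tr)

    def test_recovery_on_droplet_run(self, lpm_reference_traj):
        est = estimate_focus_center_and_params(lpm_reference_traj)
        assert np.linalg.norm(est.center) < 0.02
        assert est.r_f == pytest.approx(0.1, abs=0.025)
        assert est.D0 == pytest.approx(0.05, rel=0.2)
        assert est.A == pytest.approx(5.0, abs=0.75)

    def test_translation_equivariance(self, lpm_reference_traj):
        shift = np.array([0.05, -0.03, 0.02])
        tr = lpm_reference_traj
        moved = Trajectory(
            t=tr.t, pos=tr.pos + shift, bound=None, params=None, seed=tr.seed
        )
        a = estimate_focus_center_and_params(tr)
        b = estimate_focus_center_and_params(moved)
        np.testing.assert_allclose(b.center - a.center, shift, atol=1e-6)


@pytest.fixture(scope="module")
def pbm_dilute_traj():
    from focisim.core import Geometry, PBMParams, SimulationConfig
    from focisim.pbm import simulate_pbm

    # dilute sites (5% volume fraction): the mean-field constraint holds
    p = PBMParams(geometry=Geometry(0.1, 0.3), Db=0.0, rho=1.2e4)
    cfg = SimulationConfig(dt=1e-6, n_steps=40_000_000, seed=13, record_every=20)
    return simulate_pbm(p, cfg, start="equilibrium")


class TestMaximalPositiveDifference:
    def test_pbm_self_consistency_dilute(self, pbm_dilute_traj):
        res = maximal_positive_difference(
            pbm_dilute_traj, r_f=0.1, Db_assumed=0.0, Dn=None
        )
        assert not res.rejects_pbm()

    def test_droplet_excess_dwarfs_pbm_excess(
        self, lpm_reference_traj, pbm_static_sites_traj
    ):
        # At the typical (dense) site packing even PBM data show a small
        # positive boundary excess (the excluded-volume correction that the
        # dilute mean-field prediction neglects); the droplet's entropic
        # 'reflection' is an order of magnitude larger.
        res_pbm = maximal_positive_difference(
            pbm_static_sites_traj, r_f=0.1, Db_assumed=0.0, Dn=None
        )
        res_lpm = maximal_positive_difference(
            lpm_reference_traj, r_f=0.1, Db_assumed=0.005, Dn=1.0
        )
        assert res_lpm.rejects_pbm()
        assert res_pbm.mpd < 1e-3
        assert res_lpm.mpd > 5 * res_pbm.mpd
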
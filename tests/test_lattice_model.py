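"""Tests of the coupled phase-oscillator lattice and its integrator."""

import numpy as np
import pytest

from scnwave.lattice_model import (
    SimConfig,
    build_lattice,
    model_delta,
    run_ensemble,
    simulate,
    step,
    surface_phase,
)
from scnwave.sync_metrics import PhaseField

TWO_PI = 2 * np.pi


class TestBuild:
    def test_defect_free_lattice_has_full_count(self):
        st = build_lattice(SimConfig(seed=0, gamma=0.0))
        assert st.n_live == 20 * 20 * 10
        assert st.pacemaker.sum() == 20 * 10

    def test_drawn_frequency_spread(self):
        cfg = SimConfig(seed=1, sigma_omega=0.05)
        st = build_lattice(cfg)
        bulk = st.omega[1:, :, :]  # exclude the boosted pacemaker plane
        n = bulk.size
        se = 0.05 / np.sqrt(2 * n)
        assert bulk.std() == pytest.approx(0.05, abs=3 * se)
        assert bulk.mean() == pytest.approx(1.0, abs=3 * 0.05 / np.sqrt(n))

    def test_pacemaker_plane_is_four_percent_faster(self):
        st = build_lattice(SimConfig(seed=2, sigma_omega=0.0))
        np.testing.assert_allclose(st.omega[0], 1.04)
        np.testing.assert_allclose(st.omega[1:], 1.0)

    def test_gamma_one_empties_surface_and_display_falls_back(self):
        cfg = SimConfig(seed=3, gamma=1.0, nl=3)
        st = build_lattice(cfg)
        assert not st.live[:, :, 0].any()
        st.theta = np.broadcast_to(
            np.arange(3, dtype=float), st.theta.shape
        ).copy()  # theta == z index
        fld = surface_phase(st)
        assert fld.mask.all()
        np.testing.assert_allclose(fld.theta, 1.0)  # shows layer z=1

    def test_defect_pixel_shows_oscillator_beneath(self):
        cfg = SimConfig(seed=4, gamma=0.5, nl=2, n1=6, n2=6)
        st = build_lattice(cfg)
        st.theta = np.stack(
            [np.zeros((6, 6)) + 5.0, np.ones((6, 6))], axis=2
        )
        fld = surface_phase(st)
        dead = ~st.live[:, :, 0]
        assert dead.any() and (~dead).any()
        np.testing.assert_allclose(fld.theta[dead], 1.0)
        np.testing.assert_allclose(fld.theta[~dead], 5.0)

    def test_nl1_with_defects_masks_dead_columns(self):
        st = build_lattice(SimConfig(seed=5, gamma=0.5, nl=1, n1=8, n2=8))
        fld = surface_phase(st)
        assert (~fld.mask).sum() == (~st.live[:, :, 0]).sum()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(gamma=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(dt=-0.1).validate()
        with pytest.raises(ValueError):
            SimConfig(noise_mode="euler").validate()


class TestDynamics:
    def test_uncoupled_noiseless_phases_drift_at_omega(self, tiny_sim):
        cfg = tiny_sim.with_(coupling=0.0, t_end=2.0, transient=1.0, dtype="float64")
        st = build_lattice(cfg)
        omega_surf = st.omega[:, :, 0].copy()
        res = run_ensemble([cfg])
        np.testing.assert_allclose(
            res.final_surface_unwrapped[0], omega_surf * 2.0, rtol=1e-10
        )

    def test_homogeneous_synchronized_state_is_invariant(self, tiny_sim):
        cfg = tiny_sim.with_(sigma_omega=0.0, pacemaker_boost=1.0, coupling=0.3)
        trace = simulate(cfg)
        np.testing.assert_allclose(trace.delta, 0.0, atol=1e-5)
        np.testing.assert_allclose(trace.order_param, 1.0, atol=1e-6)

    def test_two_oscillator_locking_follows_adler_equation(self):
        """Mutual sine coupling of two oscillators: phase difference phi
        obeys dphi/dt = d_omega - 2K sin(phi), so locking requires
        |d_omega| <= 2K with lag arcsin(d_omega / 2K)."""
        K = 0.1
        base = SimConfig(n1=2, n2=1, nl=1, coupling=K, sigma_omega=0.0,
                         pacemaker_boost=1.0, t_end=400.0, transient=200.0,
                         dtype="float64", normalize_by_degree=False, seed=0)
        for d_omega, locked in [(0.1, True), (0.19, True), (0.25, False)]:
            st = build_lattice(base)
            st.omega = np.array([1.0 + d_omega, 1.0]).reshape(2, 1, 1)
            res = run_ensemble([base], [st])
            lag = (res.final_surface_unwrapped[0, 0, 0]
                   - res.final_surface_unwrapped[0, 1, 0])
            if locked:
                assert lag == pytest.approx(np.arcsin(d_omega / (2 * K)), abs=1e-4)
            else:
                # drifting: the faster oscillator laps the slower one
                assert lag > np.pi

    def test_global_rotation_symmetry(self, tiny_sim):
        cfg = tiny_sim.with_(coupling=0.2, t_end=5.0, transient=2.0, dtype="float64")
        st1 = build_lattice(cfg)
        st2 = build_lattice(cfg)
        c = 1.234
        st2.theta = st2.theta + c
        r1 = run_ensemble([cfg], [st1])
        r2 = run_ensemble([cfg], [st2])
        np.testing.assert_allclose(
            r2.final_surface_unwrapped[0], r1.final_surface_unwrapped[0] + c,
            rtol=0, atol=1e-9,
        )

    def test_rk4_convergence_is_fourth_order(self):
        """Halving dt shrinks the error by ~16x on a small lattice."""
        def final(dt):
            cfg = SimConfig(n1=5, n2=5, nl=2, coupling=0.15, dt=dt, t_end=1.0,
                            transient=0.5, dtype="float64",
                            normalize_by_degree=False, seed=9)
            return run_ensemble([cfg]).final_surface_unwrapped[0]

        ref = final(0.0025)
        e1 = np.max(np.abs(final(0.02) - ref))
        e2 = np.max(np.abs(final(0.01) - ref))
        assert 8 < e1 / e2 < 32

    def test_em_noise_variance_grows_like_2dt(self):
        """K = 0, sigma = 0, Euler-Maruyama mode: per-oscillator phase
        variance is 2 D t (the stated white-noise covariance)."""
        d_int = 0.5
        t_end = 50.0
        cfg = SimConfig(n1=20, n2=20, nl=1, coupling=0.0, sigma_omega=0.0,
                        pacemaker_boost=1.0, noise_intensity=d_int,
                        noise_mode="em", t_end=t_end, transient=25.0, seed=21)
        res = run_ensemble([cfg])
        var = np.var(res.final_surface_unwrapped[0])
        assert var == pytest.approx(2 * d_int * t_end, rel=0.2)

    def test_forcing_noise_variance_is_dt_scaled(self):
        d_int = 5.0
        t_end = 50.0
        cfg = SimConfig(n1=20, n2=20, nl=1, coupling=0.0, sigma_omega=0.0,
                        pacemaker_boost=1.0, noise_intensity=d_int,
                        noise_mode="forcing", t_end=t_end, transient=25.0, seed=22)
        res = run_ensemble([cfg])
        var = np.var(res.final_surface_unwrapped[0])
        assert var == pytest.approx(2 * d_int * cfg.dt * t_end, rel=0.2)

    def test_step_advances_time_and_matches_constant_drift(self):
        cfg = SimConfig(n1=3, n2=3, nl=1, coupling=0.0, sigma_omega=0.0,
                        pacemaker_boost=1.0, dtype="float64", seed=0)
        st = build_lattice(cfg)
        st = step(st, cfg)
        assert st.time == pytest.approx(cfg.dt)
        np.testing.assert_allclose(st.theta, cfg.dt * 1.0, rtol=1e-12)


class TestObservation:
    def test_synchronized_field_has_zero_model_delta(self):
        fld = PhaseField(theta=np.full((10, 10), 0.4))
        assert model_delta(fld) == pytest.approx(0.0, abs=1e-12)

    def test_determinism_and_batch_independence(self, tiny_sim):
        cfgs = [tiny_sim.with_(coupling=0.1, seed=s, t_end=20.0, transient=10.0)
                for s in (1, 2)]
        a = run_ensemble(cfgs)
        b = run_ensemble(cfgs)
        np.testing.assert_array_equal(a.delta, b.delta)
        solo = run_ensemble([cfgs[0]])
        np.testing.assert_array_equal(solo.delta[0], a.delta[0])

    def test_noisy_run_determinism(self, tiny_sim):
        cfg = tiny_sim.with_(noise_intensity=1.0, t_end=20.0, transient=10.0, seed=8)
        a = run_ensemble([cfg])
        b = run_ensemble([cfg])
        np.testing.assert_array_equal(a.delta, b.delta)

    def test_delta_and_r_ranges(self, tiny_sim):
        trace = simulate(tiny_sim.with_(coupling=0.1, t_end=30.0, transient=15.0))
        assert np.all(trace.delta >= 0)
        assert np.all((trace.order_param >= 0) & (trace.order_param <= 1 + 1e-9))
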
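"""Implicit stepping: assembly, linear solve, Picard iteration, marching."""

import numpy as np
import pytest

from curveflow import (
    CSF,
    ClosedCurve,
    Forcing,
    MonitorSpec,
    PicardNonConvergenceError,
    SchemeConfig,
    assemble_system,
    compute_frame,
    enclosed_area,
    evolve,
    picard_step,
)
from curveflow.solver import _monitor_and_p
from conftest import random_star_polygon, regular_ngon

UNIFORM = MonitorSpec(kind="uniform")
NO_MOTION = Forcing(alpha=0.0, beta=0.0)


def _assemble(x_prev, x_it, cfg, spec, forcing, t_next):
    frame_prev = compute_frame(x_prev)
    m_vals, p_vals = _monitor_and_p(frame_prev, spec, cfg)
    return assemble_system(x_prev, x_it, m_vals, p_vals, forcing, cfg, t_next)


class TestAssembly:
    def test_mu_value_on_inscribed_square(self):
        """Square in the unit circle: chord = 2, alpha = 1, dt = 0.01 => mu = 0.01.

        With node 0 at (1, 0) the normal is (1, 0), so the diagonal entry of
        the normal row is (1 + 2 mu) * 1.
        """
        sq = regular_ngon(4)
        cfg = SchemeConfig(scheme="BE", dt=0.01, t_final=0.1, tau=0.1)
        system = _assemble(sq, sq, cfg, UNIFORM, CSF, 0.01)
        assert system.band[3, 0] == pytest.approx(1.0 + 2 * 0.01)

    def test_dimension_and_stencil_structure(self, rng):
        """2N unknowns; each row touches only nodes {i-1, i, i+1} (periodic)."""
        curve = random_star_polygon(rng, 9)
        cfg = SchemeConfig(scheme="CNBE", dt=1e-3, t_final=1e-2, tau=0.5, p_mode="balanced")
        system = _assemble(curve, curve, cfg, MonitorSpec(kind="curvature"), CSF, 1e-3)
        n = curve.n_nodes
        dense = system.to_dense()
        assert dense.shape == (2 * n, 2 * n)
        for i in range(n):
            allowed = set()
            for j in (i - 1, i, i + 1):
                allowed |= {2 * (j % n), 2 * (j % n) + 1}
            for row in (2 * i, 2 * i + 1):
                nonzero = set(np.flatnonzero(dense[row]))
                assert nonzero <= allowed

    @pytest.mark.parametrize("scheme", ["BE", "CNBE"])
    def test_banded_solve_matches_dense_oracle(self, rng, scheme):
        curve = random_star_polygon(rng, 40)
        x_it = ClosedCurve(curve.nodes + 1e-3 * rng.standard_normal(curve.nodes.shape))
        cfg = SchemeConfig(scheme=scheme, dt=1e-3, t_final=1e-2, tau=0.5, p_mode="balanced")
        system = _assemble(curve, x_it, cfg, MonitorSpec(kind="curvature"), Forcing(1.0, 2.0), 1e-3)
        x = system.solve().ravel()
        x_ref = np.linalg.solve(system.to_dense(), system.rhs)
        np.testing.assert_allclose(x, x_ref, atol=1e-12)


class TestPicardStep:
    @pytest.mark.parametrize("scheme", ["BE", "CNBE"])
    def test_zero_velocity_fixed_point_in_one_iteration(self, scheme):
        """alpha = beta = 0, uniform monitor, regular n-gon: x^n solves exactly."""
        gon = regular_ngon(24)
        cfg = SchemeConfig(scheme=scheme, dt=0.01, t_final=0.1, tau=0.1)
        x1, iters = picard_step(gon, cfg, UNIFORM, NO_MOTION, 0.01)
        assert iters == 1
        np.testing.assert_allclose(x1.nodes, gon.nodes, atol=1e-13)

    def test_shrinking_circle_matches_scalar_radius_oracle(self):
        """By symmetry every iterate is a regular n-gon; the 2N solve must
        agree with the scalar fixed-point iteration for the radius."""
        n = 64
        phi = 2.0 * np.pi / n
        dt = 0.01
        cfg = SchemeConfig(scheme="BE", dt=dt, t_final=0.05, tau=0.1)
        x = regular_ngon(n)
        r_prev = 1.0
        for step in range(5):
            x, iters = picard_step(x, cfg, UNIFORM, CSF, (step + 1) * dt)
            radii = np.hypot(*x.nodes.T)
            assert radii.max() - radii.min() < 1e-12  # stays a regular n-gon

            # scalar oracle: substitute the n-gon ansatz into the BE stencil
            rho, oracle_iters = r_prev, 0
            for m in range(1, cfg.picard_max + 1):
                rho_new = r_prev / (
                    1.0 + 2.0 * dt * (1.0 - np.cos(phi)) / (rho**2 * np.sin(phi) ** 2)
                )
                delta, rho, oracle_iters = abs(rho_new - rho), rho_new, m
                if delta < cfg.picard_tol:
                    break
            assert radii.mean() == pytest.approx(rho, abs=1e-12)
            assert iters == oracle_iters
            r_prev = rho

    def test_matches_explicit_euler_oracle_at_tiny_dt(self):
        """One implicit BE step at dt = 1e-6 equals a forward-Euler step with
        all spatial terms at level n, to 1e-9 per node."""
        n = 64
        spec = MonitorSpec(kind="curvature")
        from curveflow import make_curve

        x0 = make_curve("ellipse", n, monitor_spec=spec)
        dt = 1e-6
        cfg = SchemeConfig(
            scheme="BE", dt=dt, t_final=dt, tau=10.0, p_mode="balanced", picard_tol=1e-13
        )
        frame = compute_frame(x0)
        m_vals, p_vals = _monitor_and_p(frame, spec, cfg)
        x1, _ = picard_step(x0, cfg, spec, CSF, dt)

        x = x0.nodes
        sec = np.roll(x, 1, axis=0) - 2.0 * x + np.roll(x, -1, axis=0)
        mu = 4.0 * dt / frame.chord_len**2
        nu = 4.0 * dt * p_vals / (cfg.tau * m_vals * frame.chord_len**2)
        m_diff = np.roll(m_vals, -1) - np.roll(m_vals, 1)
        v_n = mu * np.einsum("ij,ij->i", sec, frame.normal)
        b_t = nu * np.einsum("ij,ij->i", sec, frame.tangent) + dt * p_vals * m_diff / (
            cfg.tau * m_vals**2 * frame.chord_len
        )
        explicit = x + v_n[:, None] * frame.normal + b_t[:, None] * frame.tangent
        np.testing.assert_allclose(x1.nodes, explicit, atol=1e-9)

    def test_cap_returns_exactly_cap_iterations(self):
        gon = regular_ngon(32)
        cfg = SchemeConfig(scheme="CNBE", dt=0.01, t_final=0.1, tau=0.1, picard_cap=2)
        _, iters = picard_step(gon, cfg, UNIFORM, CSF, 0.01)
        assert iters == 2

    def test_budget_exhaustion_raises_with_time(self):
        gon = regular_ngon(32)
        cfg = SchemeConfig(
            scheme="BE", dt=0.01, t_final=0.1, tau=0.1, picard_tol=1e-16, picard_max=3
        )
        with pytest.raises(PicardNonConvergenceError) as err:
            picard_step(gon, cfg, UNIFORM, CSF, 0.01)
        assert err.value.time == pytest.approx(0.01)


class TestForcing:
    def test_negative_alpha_rejected(self):
        forcing = Forcing(alpha=-1.0)
        with pytest.raises(ValueError, match="nonnegative"):
            forcing.alpha_at(np.zeros((4, 2)), 0.0)

    def test_callable_terms_broadcast(self):
        forcing = Forcing(alpha=lambda x, t: x[:, 0] ** 2, beta=lambda x, t: t)
        pts = np.array([[1.0, 0], [2.0, 0], [0.0, 1], [0.5, 0.5]])
        np.testing.assert_allclose(forcing.alpha_at(pts, 0.3), [1, 4, 0, 0.25])
        np.testing.assert_allclose(forcing.beta_at(pts, 0.3), 0.3)


class TestEvolve:
    def test_zero_velocity_curve_is_stationary(self):
        gon = regular_ngon(24)
        cfg = SchemeConfig(scheme="CNBE", dt=0.01, t_final=0.1, tau=0.1)
        res = evolve(gon, cfg, UNIFORM, NO_MOTION)
        assert res.completed
        np.testing.assert_allclose(res.areas, res.areas[0], atol=1e-10)
        np.testing.assert_allclose(res.final_curve.nodes, gon.nodes, atol=1e-10)

    def test_series_lengths_and_snapshots(self):
        gon = regular_ngon(32)
        cfg = SchemeConfig(scheme="BE", dt=0.01, t_final=0.1, tau=0.1, snapshot_stride=4)
        res = evolve(gon, cfg, UNIFORM, CSF)
        n_steps = len(res.picard_counts)
        assert res.areas.shape[0] == n_steps + 1
        assert res.times.shape[0] == n_steps + 1
        steps = [s for s, _ in res.snapshots]
        assert steps[0] == 0 and steps[-1] == n_steps
        assert set(steps) >= {0, 4, 8, 10}

    def test_area_decreases_at_csf_rate(self):
        """dA/dt = -2 pi for any curve under V = kappa."""
        gon = regular_ngon(256)
        cfg = SchemeConfig(scheme="CNBE", dt=1e-3, t_final=0.1, tau=0.1)
        res = evolve(gon, cfg, UNIFORM, CSF)
        expected = res.areas[0] - 2.0 * np.pi * res.times
        np.testing.assert_allclose(res.areas, expected, atol=5e-4)

    def test_nonconvergence_yields_partial_singularity_result(self):
        gon = regular_ngon(32)
        cfg = SchemeConfig(
            scheme="BE", dt=0.01, t_final=0.1, tau=0.1, picard_tol=1e-16, picard_max=2
        )
        res = evolve(gon, cfg, UNIFORM, CSF)
        assert res.status == "singularity"
        assert res.failure_time == pytest.approx(0.01)
        assert res.areas.shape[0] == 1  # only the initial state completed

    def test_inconsistent_t_final_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            SchemeConfig(scheme="BE", dt=0.03, t_final=0.1, tau=0.1).n_steps


class TestSchemeConfigValidation:
    def test_bad_scheme_and_pmode(self):
        with pytest.raises(ValueError):
            SchemeConfig(scheme="RK4")
        with pytest.raises(ValueError):
            SchemeConfig(p_mode="diagonal")

    def test_cap_cannot_exceed_budget(self):
        with pytest.raises(ValueError):
            SchemeConfig(picard_cap=500, picard_max=200)
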
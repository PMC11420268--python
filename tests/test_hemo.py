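"""Flow solver: analytic benchmarks, conservation, determinism."""

import numpy as np
import pytest

from laaoflow import anatomy as an
from laaoflow import hemo


def _parabola(u_max, gap_m):
    def prof(t, y_mm):
        y = y_mm * 1e-3
        return u_max * 4.0 * y * (gap_m - y) / gap_m ** 2

    return prof


def _seed_channel(solver, state, prof):
    _, ys, _ = solver.grid.axes()
    U = state.comps[0]
    for j, y in enumerate(ys):
        U[:, j, 0] = prof(0.0, y)
    U[solver.ftype[0] == 0] = 0.0
    solver.apply_inlet(state, 0.0)


class TestStep:
    def test_zero_inflow_stays_zero(self):
        g = hemo.channel_grid(20.0, 10.0, 1.0)
        solver = hemo.FlowSolver(g, inflow=hemo.channel_inflow(lambda t, y: 0.0 * y))
        st = solver.initial_state()
        for _ in range(20):
            solver.step(st)
        assert all(np.all(st.comps[a] == 0.0) for a in range(3))

    def test_poiseuille_steady_wall_shear(self):
        # plane Poiseuille, u_max 0.1 m/s, half-gap 5 mm:
        # tau_w = 2 mu u_max / h = 0.14 Pa
        gap = 10.0
        g = hemo.channel_grid(20.0, gap, 0.625)
        props = hemo.FluidProperties()
        prof = _parabola(0.1, gap * 1e-3)
        solver = hemo.FlowSolver(g, props, hemo.SolverSettings(dt=0.005),
                                 inflow=hemo.channel_inflow(prof))
        st = solver.initial_state()
        _seed_channel(solver, st, prof)
        u_before = st.comps[0].copy()
        for _ in range(100):
            solver.step(st)
        # the seeded parabola is the steady solution
        assert np.max(np.abs(st.comps[0] - u_before)) < 2e-3
        tau = np.linalg.norm(
            hemo.wall_shear(st, g, props), axis=1)
        x = g.wall_face_table()["centroid"][:, 0]
        interior = (x > 5.0) & (x < 15.0)
        assert np.mean(tau[interior]) == pytest.approx(0.14, rel=0.05)

    def test_mass_balance_every_step(self):
        gap = 10.0
        g = hemo.channel_grid(20.0, gap, 1.0)
        solver = hemo.FlowSolver(g, inflow=hemo.channel_inflow(_parabola(0.1, gap * 1e-3)))
        st = solver.initial_state()
        solver.apply_inlet(st, 0.0)
        for _ in range(50):
            solver.step(st)
            assert solver.last_mass_residual <= 10 * solver.settings.convergence_tol
            assert solver.last_div_residual <= 1e-8

    def test_divergence_error_raised_on_nonfinite(self):
        g = hemo.channel_grid(20.0, 10.0, 1.0)
        solver = hemo.FlowSolver(g, inflow=hemo.channel_inflow(lambda t, y: 0.0 * y))
        st = solver.initial_state()
        st.comps[0][5, 5, 0] = np.nan
        with pytest.raises(hemo.SolverError, match="t="):
            solver.step(st)

    def test_womersley_oscillatory_channel(self):
        # single-harmonic oscillatory channel flow against the closed-form
        # complex solution (truncation-free oracle)
        rho, mu = 1060.0, 0.0035
        nu = mu / rho
        T = 1.01
        w = 2 * np.pi / T
        Hh = 0.005
        G = 659.0
        k = np.sqrt(1j * w / nu)

        def exact(t, y_m):
            yc = y_m - Hh
            u = (G / (rho * 1j * w)) * (1 - np.cosh(k * yc) / np.cosh(k * Hh)) \
                * np.exp(1j * w * t)
            return u.real

        g = hemo.channel_grid(20.0, 10.0, 0.5)
        solver = hemo.FlowSolver(
            g, hemo.FluidProperties(rho, mu), hemo.SolverSettings(dt=0.0025),
            inflow=hemo.channel_inflow(lambda t, y_mm: exact(t, y_mm * 1e-3)))
        st = solver.initial_state()
        _, ys, _ = g.axes()
        _seed_channel(solver, st, lambda t, y_mm: exact(0.0, y_mm * 1e-3))
        dt = 0.0025
        n = int(round(2 * T / dt))
        mid = g.shape[0] // 2
        num_sq = den_sq = 0.0
        for i in range(n):
            solver.step(st, dt)
            if st.t > T:
                ex = exact(st.t, ys[1:-1] * 1e-3)
                got = 0.5 * (st.comps[0][mid, 1:-1, 0] + st.comps[0][mid + 1, 1:-1, 0])
                num_sq += float(np.sum((got - ex) ** 2))
                den_sq += float(np.sum(ex ** 2))
        assert np.sqrt(num_sq / den_sq) < 0.05

    def test_poiseuille_shear_error_decreases_under_refinement(self):
        gap = 10.0
        props = hemo.FluidProperties()
        errs = []
        for h in (2.0, 1.0, 0.5):
            g = hemo.channel_grid(20.0, gap, h)
            prof = _parabola(0.1, gap * 1e-3)
            solver = hemo.FlowSolver(g, props, hemo.SolverSettings(dt=0.002),
                                     inflow=hemo.channel_inflow(prof))
            st = solver.initial_state()
            _seed_channel(solver, st, prof)
            for _ in range(20):
                solver.step(st)
            tau = np.linalg.norm(hemo.wall_shear(st, g, props), axis=1)
            x = g.wall_face_table()["centroid"][:, 0]
            interior = (x > 5.0) & (x < 15.0)
            errs.append(abs(np.mean(tau[interior]) - 0.14) / 0.14)
        assert errs[0] > errs[1] > errs[2]

    def test_kinetic_energy_bounded_over_cycles(self):
        wf = hemo.AfWaveform()
        g = hemo.channel_grid(20.0, 10.0, 1.0)
        solver = hemo.FlowSolver(
            g, inflow=hemo.channel_inflow(lambda t, y: np.full_like(y, wf.velocity(t))))
        st = solver.initial_state()
        solver.apply_inlet(st, 0.0)
        ke = []
        for i in range(400):
            solver.step(st)
            ke.append(solver.kinetic_energy(st))
        ke = np.array(ke)
        assert np.all(np.isfinite(ke))
        # periodic forcing: late-time energy stays within the forced band
        assert ke[200:].max() < 5 * ke[:200].max()

    def test_determinism(self):
        wf = hemo.AfWaveform()

        def run():
            g = hemo.channel_grid(20.0, 10.0, 1.0)
            solver = hemo.FlowSolver(
                g, inflow=hemo.channel_inflow(lambda t, y: np.full_like(y, wf.velocity(t))))
            st = solver.initial_state()
            for _ in range(30):
                solver.step(st)
            return st

        a, b = run(), run()
        assert all(np.array_equal(a.comps[x], b.comps[x]) for x in range(3))
        assert np.array_equal(a.p, b.p)


class TestWallShear:
    def test_linear_shear_exact(self):
        # u = (gamma*y, 0, 0): tau = mu*gamma exactly on the bottom wall
        g = hemo.channel_grid(20.0, 10.0, 1.0)
        props = hemo.FluidProperties()
        solver = hemo.FlowSolver(g, props, inflow={})
        st = solver.initial_state()
        gamma = 12.0
        _, ys, _ = g.axes()
        for j, y in enumerate(ys):
            st.comps[0][:, j, 0] = gamma * y * 1e-3
        tab = g.wall_face_table()
        tau = hemo.wall_shear(st, g, props, tab)
        bottom = (tab["normal"][:, 1] < 0) & (tab["centroid"][:, 0] > 3) \
            & (tab["centroid"][:, 0] < 17)
        assert np.allclose(np.linalg.norm(tau[bottom], axis=1),
                           props.dynamic_viscosity * gamma, rtol=1e-12)

    def test_quiescent_fluid_zero(self, coarse_grid):
        solver_props = hemo.FluidProperties()
        comps = {}
        for a in range(3):
            shape = list(coarse_grid.shape)
            shape[a] += 1
            comps[a] = np.zeros(shape)
        st = hemo.FlowState(t=0.0, comps=comps, p=np.zeros(coarse_grid.shape))
        tau = hemo.wall_shear(st, coarse_grid, solver_props)
        assert np.all(tau == 0.0)

    def test_tangential_to_face(self, coarse_grid, rng):
        comps = {}
        for a in range(3):
            shape = list(coarse_grid.shape)
            shape[a] += 1
            comps[a] = rng.normal(size=shape) * 0.01
        st = hemo.FlowState(t=0.0, comps=comps, p=np.zeros(coarse_grid.shape))
        tab = coarse_grid.wall_face_table()
        tau = hemo.wall_shear(st, coarse_grid, hemo.FluidProperties(), tab)
        assert np.allclose(np.sum(tau * tab["normal"], axis=1), 0.0, atol=1e-12)


class TestReynolds:
    def test_arithmetic(self):
        props = hemo.FluidProperties()
        assert hemo.reynolds_number(0.5, 0.010, props) == pytest.approx(1514.3, rel=1e-3)
        assert hemo.reynolds_number(0.0, 0.010, props) == 0.0

    def test_parabolic_profile_mean_from_face_fluxes(self):
        # plane-channel parabolic profile: cross-section mean is 2/3 u_max
        # (u_max/2 for a circular tube); the face-flux quadrature must
        # recover the closed form
        gap = 10.0
        g = hemo.channel_grid(20.0, gap, 0.25)
        props = hemo.FluidProperties()
        u_max = 0.2
        prof = _parabola(u_max, gap * 1e-3)
        solver = hemo.FlowSolver(g, props, inflow=hemo.channel_inflow(prof))
        st = solver.initial_state()
        solver.apply_inlet(st, 0.0)
        ft, lf = g.face_classes()[0]
        m = ft == an.FACE_INLET0
        q = float(np.sum(st.comps[0][m])) * (g.spacing * 1e-3)
        mean_u = q / (gap * 1e-3)  # per unit depth
        assert mean_u == pytest.approx(2.0 / 3.0 * u_max, rel=0.01)

    def test_waveform_nonnegative_and_periodic(self):
        wf = hemo.AfWaveform()
        t = np.linspace(0, 3 * wf.cycle_period, 3001)
        v = wf.velocity(t)
        assert np.all(v >= 0)
        assert np.allclose(wf.velocity(t), wf.velocity(t + wf.cycle_period))

    def test_protocol_step_counts(self):
        # reference protocol arithmetic: 10 warm-up and 6 evaluation cycles
        # of 1.01 s at dt = 0.005 s
        wf = hemo.AfWaveform()
        s = hemo.SolverSettings(dt=0.005, warmup_cycles=10, eval_cycles=6)
        per_cycle = round(wf.cycle_period / s.dt)
        assert per_cycle == 202
        assert s.warmup_cycles * per_cycle == 2020
        assert s.eval_cycles * per_cycle == 1212
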
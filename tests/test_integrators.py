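"""Velocity-Verlet and BAOAB stepping, temperature and energy reporting."""

import numpy as np
import pytest

from conftest import small_state
from sgmd import forcefield, groups, integrators, protocols
from sgmd.integrators import ThermoParams


class TestVelocityVerlet:
    def test_free_flight(self):
        st = small_state("p1", n=1, density=0.01, radius=1)
        st.asym_vel[0] = [1.0, 0.0]
        x0 = st.asym_pos[0].copy()
        integrators.step_nve(st, ThermoParams(dt=0.005))
        assert np.allclose(st.asym_pos[0], x0 + [0.005, 0.0], atol=1e-14)

    def test_harmonic_oscillator_period_and_energy(self, monkeypatch):
        """With a harmonic force field (k = 1), VV reproduces the analytic
        period to 0.1% and the energy error stays O(dt^2)."""

        def harmonic(state):
            return 0.5 * float(np.sum(state.asym_pos**2)), -state.asym_pos

        monkeypatch.setattr(forcefield, "energy_and_forces", harmonic)
        st = small_state("p1", n=1, density=0.01, radius=1)
        st.asym_pos[:] = [[1.0, 0.0]]
        st.asym_vel[:] = 0.0
        dt = 0.005
        params = ThermoParams(dt=dt)
        period_steps = int(round(2 * np.pi / dt))
        xs = []
        for _ in range(period_steps + 10):
            integrators._vv_step(st, params, harmonic(st)[1], 0)
            xs.append(st.asym_pos[0, 0])
        # crossing of maximum near one full period
        k = int(np.argmax(xs[period_steps - 10 : period_steps + 10]))
        measured = (period_steps - 10 + k + 1) * dt
        assert measured == pytest.approx(2 * np.pi, rel=1e-3)
        e_end = 0.5 * float(np.sum(st.asym_vel**2) + np.sum(st.asym_pos**2))
        assert abs(e_end - 0.5) < 0.5 * dt**2 * 10

    def test_constrained_p2_equals_full_unconstrained_dynamics(self):
        """Central correctness property: from a symmetric start the
        constrained asymmetric-unit trajectory coincides with the full
        unconstrained trajectory of the same particles."""
        g = groups.load_group("p2", 2)
        st = protocols.build_initial_state(
            g, 2, 0.3, temperature=0.3, seed=7, image_radius=2
        )
        full = protocols._expanded_cell_state(st, 2)
        B, Binv = st.box, np.linalg.inv(st.box)
        vel = [
            st.asym_vel[i] @ (Binv @ op.linear.T @ B)
            for i in range(st.n)
            for op in g.elements
        ]
        full.asym_vel = np.array(vel)
        params = ThermoParams(dt=0.005)
        integrators.run_md(st, 100, params)
        integrators.run_md(full, 100, params)
        mine = full.asym_pos.reshape(st.n, len(g), 2)[:, 0, :]
        assert np.max(np.abs(st.asym_pos - mine)) < 1e-8


class TestBAOAB:
    def test_gamma_zero_reduces_to_velocity_verlet(self):
        a = small_state("p4", n=2, temperature=0.5, seed=9)
        b = a.copy()
        nve = ThermoParams(dt=0.005)
        nvt = ThermoParams(dt=0.005, gamma=0.0, temperature=0.5)
        rng = np.random.default_rng(0)
        integrators.run_md(a, 50, nve, ensemble="nve")
        integrators.run_md(b, 50, nvt, ensemble="nvt", rng=rng)
        assert np.max(np.abs(a.asym_pos - b.asym_pos)) < 1e-12

    def test_free_particle_samples_maxwell_boltzmann(self, monkeypatch):
        """OU stationary distribution: <v^2> per component = T/m."""

        def no_force(state):
            return 0.0, np.zeros_like(state.asym_pos)

        monkeypatch.setattr(forcefield, "energy_and_forces", no_force)
        st = small_state("p1", n=1, density=0.01, radius=1)
        T = 0.5
        params = ThermoParams(dt=0.005, gamma=2.0, temperature=T)
        rng = np.random.default_rng(12)
        vs = []
        f = np.zeros_like(st.asym_pos)
        for step in range(40_000):
            f = integrators._baoab_step(st, params, f, rng, step)
            if step > 2000 and step % 10 == 0:
                vs.append(st.asym_vel[0].copy())
        vs = np.asarray(vs).ravel()
        se = np.std(vs**2) / np.sqrt(len(vs) / 20)  # crude autocorr margin
        assert abs(np.mean(vs**2) - T) < 3 * se

    def test_same_seed_same_trajectory(self):
        a = small_state("p4", n=2, temperature=0.5, seed=9)
        b = a.copy()
        params = ThermoParams(dt=0.005, gamma=0.1, temperature=0.5)
        integrators.run_md(a, 40, params, ensemble="nvt",
                           rng=np.random.default_rng(5))
        integrators.run_md(b, 40, params, ensemble="nvt",
                           rng=np.random.default_rng(5))
        assert np.array_equal(a.asym_pos, b.asym_pos)
        assert np.array_equal(a.asym_vel, b.asym_vel)


class TestReporting:
    def test_temperature_examples(self):
        st = small_state("p1", n=1, density=0.01, radius=1)
        st.asym_vel[:] = 0.0
        assert integrators.temperature(st) == 0.0
        st.asym_vel[0] = [1.0, 0.0]
        assert integrators.temperature(st, dof=2) == pytest.approx(0.5)
        st.mass[:] = 2.0
        assert integrators.temperature(st, dof=2) == pytest.approx(1.0)

    def test_energy_report_at_rest_far_apart(self):
        st = small_state("p2", n=1, density=0.001, radius=1)
        st.asym_vel[:] = 0.0
        assert integrators.total_energy_report(st) == (0.0, 0.0, 0.0)

    def test_p1_kinetic_is_plain(self):
        st = small_state("p1", n=3, temperature=0.5, seed=1)
        ke, _, _ = integrators.total_energy_report(st)
        assert ke == pytest.approx(
            0.5 * float(np.sum(st.asym_vel**2)), abs=1e-12
        )

    def test_divergence_detection(self):
        st = small_state("p1", n=1, density=0.01, radius=1)
        st.asym_vel[0] = [1e7, 0.0]
        with pytest.raises(integrators.DivergenceError, match="diverged"):
            integrators.run_md(st, 2, ThermoParams(dt=0.005))
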
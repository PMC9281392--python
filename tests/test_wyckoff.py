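"""Lagrange-multiplier constraints holding particles on Wyckoff positions."""

import numpy as np
import pytest

from sgmd import groups, integrators, protocols, wyckoff_constraints as wc


@pytest.fixture(scope="module")
def pmm():
    return groups.load_group("pmm", 2)


def line_site(g):
    return next(
        s
        for s in g.wyckoff_sites
        if s.site_dof == 1
        and np.allclose(s.anchor, [0, 0])
        and abs(s.directions[1, 0]) > 0.5  # free along y: the x = 0 line
    )


def make(g, site, s0):
    return wc.make_constraint(0, site, np.asarray(s0, dtype=float))


class TestResidual:
    def test_line_site_residual(self, pmm):
        c = make(pmm, line_site(pmm), [0.0, 0.7])
        box = np.eye(2)
        res = wc.sigma(np.array([0.3, 0.7]), c, box)
        assert res.shape == (1,)
        assert abs(abs(res[0]) - 0.3) < 1e-12

    def test_zero_on_site(self, pmm):
        c = make(pmm, line_site(pmm), [0.0, 0.7])
        assert np.allclose(wc.sigma(np.array([0.0, 0.13]), c, np.eye(2)), 0.0)

    def test_zero_after_projection(self, pmm):
        site = line_site(pmm)
        c = make(pmm, site, [0.0, 0.7])
        box = np.array([[2.0, 0.0], [0.0, 3.0]])
        q = np.array([0.41, 1.93])
        proj = wc.project_position(q, c, box)
        assert np.allclose(wc.sigma(proj, c, box), 0.0, atol=1e-12)

    def test_off_branch_assignment_rejected(self, pmm):
        with pytest.raises(ValueError, match="not on Wyckoff site"):
            make(pmm, line_site(pmm), [0.3, 0.7])


class TestMultipliers:
    def test_zero_lambda_zero_force(self, pmm):
        c = make(pmm, line_site(pmm), [0.0, 0.5])
        assert np.allclose(wc.constraint_force(np.zeros(1), c, np.eye(2)), 0.0)

    def test_one_dimensional_closed_form(self, pmm):
        """Line x = 0 in a unit box: unconstrained x' = 0.3 gives
        lambda = (m/dt^2) * 0.3 up to the Jacobian sign, and the corrected
        position lands exactly on the site."""
        c = make(pmm, line_site(pmm), [0.0, 0.5])
        dt, m = 0.005, 1.0
        q = np.array([0.3, 0.5])
        lam = wc.solve_lambda(q, c, np.eye(2), dt, m)
        assert abs(lam[0]) == pytest.approx((m / dt**2) * 0.3, rel=1e-12)
        corrected = q + (dt**2 / m) * wc.constraint_force(lam, c, np.eye(2))
        assert np.allclose(wc.sigma(corrected, c, np.eye(2)), 0.0, atol=1e-12)

    def test_random_sites_exact_in_one_step(self):
        from sgmd.lattice import make_projector

        rng = np.random.default_rng(4)
        for name in ("p4m", "p6m", "cmm"):
            g = groups.load_group(name, 2)
            box = make_projector(g.bravais_class, 2)(np.eye(2) * 2.1)
            for site in g.wyckoff_sites:
                s0 = groups.project_to_wyckoff(rng.random(2), site)
                c = wc.make_constraint(0, site, s0)
                q = rng.normal(size=2) @ box
                lam = wc.solve_lambda(q, c, box, 0.005, 1.0)
                corrected = q + (0.005**2 / 1.0) * wc.constraint_force(
                    lam, c, box
                )
                assert np.max(np.abs(wc.sigma(corrected, c, box))) < 1e-10

    def test_constraint_force_does_no_tangential_work(self, pmm):
        c = make(pmm, line_site(pmm), [0.0, 0.5])
        box = np.array([[1.9, 0.0], [0.0, 2.3]])
        f = wc.constraint_force(np.array([2.0]), c, box)
        for t in c.tangent_rows(box):
            assert abs(f @ t) < 1e-12


class TestDof:
    def test_unconstrained(self):
        assert wc.degrees_of_freedom(5, 2) == 10

    def test_line_removes_one_point_removes_two(self, pmm):
        line = make(pmm, line_site(pmm), [0.0, 0.5])
        point = make(pmm, pmm.site("1a"), [0.0, 0.0])
        assert line.removed_dof == 1
        assert point.removed_dof == 2
        assert wc.removed_dof_total([line, point]) == 3


class TestDynamics:
    def test_residual_stays_machine_zero_through_nvt(self):
        """Short NVT with one particle on a line site and one general
        particle: the site residual never exceeds 1e-10."""
        state = protocols.build_initial_state(
            "pmm", 1, 0.3, wyckoff_sites=["2e"], temperature=0.3, seed=2,
            image_radius=1,
        )
        cons = integrators._constraints(state)
        assert len(cons) == 1
        worst = 0.0

        def track(step, st):
            nonlocal worst
            for c in cons:
                worst = max(
                    worst,
                    np.max(np.abs(wc.sigma(st.asym_pos[c.particle_index], c, st.box))),
                )

        params = integrators.ThermoParams(dt=0.005, gamma=0.1, temperature=0.3)
        integrators.run_md(
            state, 300, params, ensemble="nvt",
            rng=np.random.default_rng(0), callback=track,
        )
        assert worst < 1e-10

    def test_point_site_particle_never_moves(self):
        state = protocols.build_initial_state(
            "p4", 1, 0.3, wyckoff_sites=["1a"], temperature=0.5, seed=3,
            image_radius=1,
        )
        x0 = state.asym_pos[0].copy()
        params = integrators.ThermoParams(dt=0.005, gamma=0.1, temperature=0.5)
        integrators.run_md(
            state, 100, params, ensemble="nvt", rng=np.random.default_rng(1)
        )
        assert np.allclose(state.asym_pos[0], x0, atol=1e-12)

    def test_nve_conservation_with_constraint(self):
        """Energy conservation quality is not degraded by an active
        line-site constraint."""
        state = protocols.build_initial_state(
            "pmm", 1, 0.25, wyckoff_sites=["2e"], temperature=0.4, seed=5,
            image_radius=1,
        )
        params = integrators.ThermoParams(dt=0.005)
        rec = np.asarray(
            integrators.run_md(state, 1500, params, record_every=10)
        )
        e = rec[:, 3]
        assert np.max(np.abs(e - e[0])) < 0.05 * max(1.0, abs(e[0]))
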
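"""Group tables, orbit algebra, Wyckoff sites and asymmetric-unit sampling."""

import numpy as np
import pytest

from sgmd import groups
from sgmd.groups import (
    GroupNotBundledError,
    SpecialPositionError,
    expand_unit_cell,
    load_group,
    orbit,
    project_to_wyckoff,
    sample_asymmetric_unit,
    wrap_frac,
)

from conftest import PLANAR_MULTIPLICITY


def set_distance(a, b):
    """Hausdorff-style max-min distance between two fractional point sets,
    modulo lattice translations."""
    d = a[:, None, :] - b[None, :, :]
    d -= np.round(d)
    pair = np.linalg.norm(d, axis=-1)
    return max(pair.min(axis=1).max(), pair.min(axis=0).max())


class TestLoading:
    def test_multiplicity_matches_standard_tables(self, planar_group):
        assert len(planar_group) == PLANAR_MULTIPLICITY[planar_group.identifier]

    def test_exactly_one_identity(self, planar_group):
        ids = [op for op in planar_group.elements if op.is_identity()]
        assert len(ids) == 1 and planar_group.elements[0].is_identity()

    def test_closure(self, planar_group):
        keys = {op._key() for op in planar_group.elements}
        for a in planar_group.elements:
            for b in planar_group.elements:
                assert a.compose(b)._key() in keys

    def test_unimodular(self, planar_group):
        for op in planar_group.elements:
            assert abs(abs(np.linalg.det(op.linear)) - 1.0) < 1e-12

    def test_sg127_order_16(self, sg127):
        assert len(sg127) == 16

    def test_sg127_matches_gemmi_tables(self, sg127):
        """Cross-validate the bundled 3D group against an independent
        crystallographic library."""
        import gemmi

        ref = {
            (tuple(np.array(op.rot).ravel()), tuple(op.tran))
            for op in gemmi.find_spacegroup_by_number(127).operations()
        }
        den = gemmi.Op.DEN
        ours = {
            (
                tuple(np.round(op.linear.ravel() * den).astype(int)),
                tuple(np.round(op.translation * den).astype(int) % den),
            )
            for op in sg127.elements
        }
        assert ours == ref

    def test_unknown_group_lists_available(self):
        with pytest.raises(GroupNotBundledError, match="p6m"):
            load_group("p7", 2)

    def test_dimension_mismatch(self):
        with pytest.raises(GroupNotBundledError):
            load_group(127, 2)


class TestOrbits:
    def test_identity_group_orbit(self):
        g = load_group("p1", 2)
        assert np.allclose(orbit([0.3, 0.4], g), [[0.3, 0.4]])

    def test_p2_inversion_orbit(self):
        g = load_group("p2", 2)
        got = orbit([0.25, 0.25], g)
        assert np.allclose(sorted(map(tuple, got)), [[0.25, 0.25], [0.75, 0.75]])

    def test_general_orbit_has_group_order_distinct_points(self, sg127):
        pts = orbit([0.11, 0.23, 0.37], sg127)
        assert len(pts) == 16
        d = pts[:, None, :] - pts[None, :, :]
        d -= np.round(d)
        r = np.linalg.norm(d, axis=-1) + np.eye(16)
        assert r.min() > 1e-6

    def test_orbit_starts_with_seed_point(self, planar_group):
        q = np.array([0.123, 0.271])
        assert np.allclose(orbit(q, planar_group)[0], q)

    def test_expand_127_five_general_gives_80(self, sg127):
        rng = np.random.default_rng(0)
        pts = sample_asymmetric_unit(sg127, 5, rng_seed=1)
        assert expand_unit_cell(pts, sg127).shape == (80, 3)

    def test_expand_trivial_and_p2(self):
        p1 = load_group("p1", 2)
        pts = np.array([[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]])
        assert np.allclose(expand_unit_cell(pts, p1), pts)
        p2 = load_group("p2", 2)
        out = expand_unit_cell(pts[:2], p2)
        assert out.shape == (4, 2)
        for k in range(2):
            assert np.allclose(
                wrap_frac(-out[2 * k]), out[2 * k + 1], atol=1e-12
            )

    def test_expand_rejects_special_position(self):
        p2 = load_group("p2", 2)
        with pytest.raises(SpecialPositionError, match="Wyckoff"):
            expand_unit_cell(np.array([[0.5, 0.5]]), p2)

    def test_group_elements_permute_unit_cell(self, planar_group):
        """Applying any element to the full expanded cell reproduces the
        same point set: the symmetry of the configuration is exact."""
        rng = np.random.default_rng(7)
        pts = sample_asymmetric_unit(planar_group, 2, rng_seed=5)
        cell = expand_unit_cell(pts, planar_group)
        for op in planar_group.elements:
            moved = wrap_frac(op(cell))
            assert set_distance(moved, cell) < 1e-10


class TestWyckoff:
    def test_projector_idempotent(self, planar_group):
        rng = np.random.default_rng(11)
        for site in planar_group.wyckoff_sites:
            q = rng.random((100, 2))
            once = site.projector(q)
            assert np.allclose(site.projector(once), once, atol=1e-10)

    def test_projected_points_are_fixed_by_stabilizer(self, planar_group):
        rng = np.random.default_rng(3)
        for site in planar_group.wyckoff_sites:
            p = project_to_wyckoff(rng.random(2), site)
            stab = planar_group.stabilizer_of(p)
            assert len(stab) >= len(site.stabilizer)
            assert site.multiplicity * len(site.stabilizer) == len(planar_group)

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("p2", {("1a", 0), ("1b", 0), ("1c", 0), ("1d", 0)}),
            ("pg", set()),
            ("p4", {("1a", 0), ("1b", 0), ("2c", 0)}),
            (
                "p6m",
                {("1a", 0), ("2b", 0), ("3c", 0), ("6d", 1), ("6e", 1)},
            ),
        ],
    )
    def test_known_wyckoff_site_inventories(self, name, expected):
        g = load_group(name, 2)
        assert {(s.label, s.site_dof) for s in g.wyckoff_sites} == expected

    def test_sg127_has_eleven_sites(self, sg127):
        mults = sorted(s.multiplicity for s in sg127.wyckoff_sites)
        assert mults == [2, 2, 2, 2, 4, 4, 4, 4, 8, 8, 8]

    def test_line_projection_example(self):
        g = load_group("pmm", 2)
        site = next(
            s
            for s in g.wyckoff_sites
            if s.site_dof == 1 and np.allclose(s.anchor, [0, 0])
            and abs(s.directions[1, 0]) > 0.5
        )
        assert np.allclose(project_to_wyckoff([0.3, 0.7], site), [0.0, 0.7])

    def test_point_projection_example(self):
        g = load_group("p2", 2)
        site = g.site("1a")
        assert np.allclose(project_to_wyckoff([0.3, 0.7], site), [0.0, 0.0])


class TestSampling:
    def test_points_satisfy_asymmetric_unit_predicate(self, planar_group):
        pts = sample_asymmetric_unit(planar_group, 4, rng_seed=9)
        assert all(planar_group.asym_unit(p) for p in pts)

    def test_deterministic(self):
        g = load_group("p4", 2)
        a = sample_asymmetric_unit(g, 4, rng_seed=13)
        b = sample_asymmetric_unit(g, 4, rng_seed=13)
        assert np.array_equal(a, b)

    def test_minimum_separation_enforced(self):
        g = load_group("p4", 2)
        box = np.eye(2) * 4.0
        pts = sample_asymmetric_unit(g, 3, rng_seed=1, box=box, min_sep=0.9)
        cell = expand_unit_cell(pts, g) @ box
        r = np.linalg.norm(cell[:, None] - cell[None, :], axis=-1)
        r[r < 1e-12] = np.inf
        assert r.min() >= 0.9

    def test_impossible_packing_raises(self):
        g = load_group("p6m", 2)
        with pytest.raises(RuntimeError, match="lower n or the density"):
            sample_asymmetric_unit(
                g, 20, rng_seed=1, box=np.eye(2), min_sep=0.9, max_attempts=500
            )

    def test_fundamental_domain_measure(self):
        """The canonical-representative region has measure 1/|G|."""
        g = load_group("p4", 2)
        rng = np.random.default_rng(21)
        hits = sum(g.asym_unit(s) for s in rng.random((4000, 2)))
        frac = hits / 4000
        assert abs(frac - 1 / len(g)) < 0.03
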
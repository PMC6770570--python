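"""Geometry primitives: superposition, axes, Rg, dihedrals, helix rule."""

import biotite.structure as bst
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from encompass.errors import DegenerateGeometryError
from encompass.geomcore import (
    OrientedAxis,
    assign_helix,
    axis_angle,
    backbone_dihedrals,
    radius_of_gyration,
    rmsd_no_fit,
    segment_axis,
    superpose,
)
from encompass.synthgen import make_ideal_helix

from .oracles import grid_superpose_rmsd, random_rotation

TETRAHEDRON = np.array([
    [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
])


class TestSuperpose:
    def test_identity(self):
        _, rmsd = superpose(TETRAHEDRON, TETRAHEDRON)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_recovered(self, rng):
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = TETRAHEDRON @ Rz.T + np.array([5.0, 0.0, 0.0])
        transform, rmsd = superpose(moved, TETRAHEDRON)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(transform.apply(moved), TETRAHEDRON,
                                   atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(scale=2.0, size=(6, 3))
        b = rng.normal(scale=2.0, size=(6, 3))
        _, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(grid_superpose_rmsd(a, b), abs=1e-3)

    def test_matches_biotite(self, rng):
        a = rng.normal(size=(12, 3))
        R = random_rotation(rng)
        b = (a + rng.normal(scale=0.4, size=a.shape)) @ R.T + 3.0
        _, rmsd = superpose(b, a)
        fitted, _ = bst.superimpose(a, b)
        expected = float(np.sqrt(((fitted - a) ** 2).sum(axis=1).mean()))
        # biotite carries float32 coordinates, so agreement is ~1e-7
        assert rmsd == pytest.approx(expected, abs=1e-6)

    def test_rejects_reflection(self, rng):
        a = rng.normal(size=(8, 3))
        mirrored = a * np.array([1.0, 1.0, -1.0])
        transform, rmsd = superpose(mirrored, a)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)
        assert rmsd > 0.1  # a reflection would give 0 here

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateGeometryError):
            superpose(TETRAHEDRON[:2], TETRAHEDRON[:2])
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rmsd_symmetric_and_rigid_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        _, r_ab = superpose(a, b)
        _, r_ba = superpose(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        R = random_rotation(rng)
        t = rng.normal(size=3)
        _, r_moved = superpose(a @ R.T + t, b @ R.T + t)
        assert r_moved == pytest.approx(r_ab, abs=1e-9)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_no_fit_rmsd_bounds_fitted(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        _, fitted = superpose(a, b)
        assert rmsd_no_fit(a, b) >= fitted - 1e-12


class TestRmsdNoFit:
    def test_identical(self):
        assert rmsd_no_fit(TETRAHEDRON, TETRAHEDRON) == 0.0

    def test_uniform_translation(self):
        assert rmsd_no_fit(
            TETRAHEDRON, TETRAHEDRON + np.array([3.0, 4.0, 0.0])
        ) == pytest.approx(5.0)

    def test_matches_direct_formula(self, rng):
        a = rng.normal(size=(9, 3))
        b = rng.normal(size=(9, 3))
        direct = np.sqrt(sum(np.sum((p - q) ** 2) for p, q in zip(a, b)) / 9)
        assert rmsd_no_fit(a, b) == pytest.approx(direct, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rmsd_no_fit(TETRAHEDRON, TETRAHEDRON[:3])


class TestSegmentAxis:
    def test_ideal_helix_axis(self):
        # 19 residues = 18 steps of 100° twist = 5 full turns, so the
        # end-to-end chord coincides with the construction axis
        helix = make_ideal_helix(19)
        ca = helix.coords[helix.atom_names == "CA"].astype(float)
        chord = ca[-1] - ca[0]
        chord /= np.linalg.norm(chord)
        construction = OrientedAxis(chord, ca.mean(axis=0))
        # whole turns: the principal direction is the construction axis
        assert axis_angle(segment_axis(ca), construction) < 1.0
        # a 10-residue window covers 2.5 turns; the unbalanced phase tilts
        # the principal direction by ~6°, still far inside a 30° filter
        assert axis_angle(segment_axis(ca[:10]), construction) < 10.0

    def test_reversal_flips_sign(self):
        helix = make_ideal_helix(10)
        ca = helix.coords[helix.atom_names == "CA"]
        fwd = segment_axis(ca)
        rev = segment_axis(ca[::-1])
        assert axis_angle(fwd, rev) == pytest.approx(180.0, abs=1e-6)

    def test_straight_line_exact(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        axis = segment_axis(line)
        np.testing.assert_allclose(axis.direction, [1.0, 0.0, 0.0],
                                   atol=1e-12)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            segment_axis(np.zeros((3, 3)))


class TestAxisAngle:
    def test_self_zero_and_negation_180(self):
        a = OrientedAxis(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        assert axis_angle(a, a) == 0.0
        assert axis_angle(a, a.negate()) == pytest.approx(180.0)

    def test_30_degree_rotation(self):
        a = OrientedAxis(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        t = np.radians(30.0)
        b = OrientedAxis(np.array([np.sin(t), 0.0, np.cos(t)]), np.zeros(3))
        assert axis_angle(a, b) == pytest.approx(30.0, abs=1e-6)

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_negation_complements_to_180(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=(2, 3))
        a = OrientedAxis(u / np.linalg.norm(u), np.zeros(3))
        b = OrientedAxis(v / np.linalg.norm(v), np.zeros(3))
        assert axis_angle(a, b) + axis_angle(a, b.negate()) == \
            pytest.approx(180.0, abs=1e-9)


class TestRadiusOfGyration:
    def test_single_point(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_points(self):
        pts = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(pts) == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        pts = rng.normal(size=(20, 3))
        masses = rng.uniform(1.0, 16.0, size=20)
        w = masses / masses.sum()
        com = w @ pts
        direct = np.sqrt(np.sum(w * np.sum((pts - com) ** 2, axis=1)))
        assert radius_of_gyration(pts, masses) == pytest.approx(
            direct, abs=1e-12
        )

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariant(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 3))
        R = random_rotation(rng)
        moved = pts @ R.T + rng.normal(size=3)
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(pts), abs=1e-9
        )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((2, 3)), np.array([1.0, 0.0]))


class TestHelixAssignment:
    def test_canonical_run_is_helical(self):
        pp = np.tile([-57.0, -47.0], (10, 1))
        helical = assign_helix(pp)
        assert helical.all()

    def test_outside_window_not_helical(self):
        pp = np.tile([-120.0, 120.0], (10, 1))
        assert not assign_helix(pp).any()

    def test_short_run_suppressed(self):
        pp = np.tile([-120.0, 120.0], (10, 1))
        pp[3:6] = [-57.0, -47.0]  # run of 3 < minimum run of 4
        assert not assign_helix(pp).any()

    def test_nan_dihedrals_non_helical(self):
        pp = np.tile([-57.0, -47.0], (6, 1))
        pp[0, 0] = np.nan
        helical = assign_helix(pp)
        assert not helical[0] and helical[1:].all()

    def test_ideal_helix_dihedrals(self):
        helix = make_ideal_helix(10)
        res_ids, phi, psi = backbone_dihedrals(helix)
        assert np.isnan(phi[0]) and np.isnan(psi[-1])
        np.testing.assert_allclose(phi[1:], -57.0, atol=0.1)
        np.testing.assert_allclose(psi[:-1], -47.0, atol=0.1)
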
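import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_min_distance, quaternion_rmsd, random_rigid_transform
from pepdimer import synthetic as syn
from pepdimer.errors import DegenerateGeometryError
from pepdimer.geometry import (
    buried_hydrophobic_area,
    center_of_mass,
    end_to_end_distance,
    kabsch_superpose,
    min_contact_distance,
    radius_of_gyration,
    ring_orientation_angle,
    rmsd_after_fit,
    shrake_rupley_sasa,
    vdw_radii,
)


class TestKabsch:
    def test_identical_coordinates_give_zero_rmsd_and_identity(self, rng):
        x = rng.normal(size=(12, 3))
        sup = kabsch_superpose(x, x)
        assert sup.rmsd < 1e-10
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-8)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_rigid_transform_is_removed_exactly(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(10, 3))
        rot, trans = random_rigid_transform(rng)
        sup = kabsch_superpose(x, x @ rot.T + trans)
        assert sup.rmsd < 1e-8
        assert abs(np.linalg.det(sup.rotation) - 1.0) < 1e-8

    def test_agrees_with_quaternion_oracle(self, rng):
        for _ in range(10):
            p = rng.normal(size=(8, 3))
            q = p.copy()
            q[0] += rng.normal(size=3)
            assert kabsch_superpose(p, q).rmsd == pytest.approx(
                quaternion_rmsd(p, q), abs=1e-10
            )

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    def test_fewer_than_three_points_rejected(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(x, x, subset=[0, 1])


class TestRmsdAfterFit:
    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 15, 3))
        assert rmsd_after_fit(a, b) == pytest.approx(rmsd_after_fit(b, a), abs=1e-10)

    def test_triangle_like_bound(self, rng):
        a, b, c = rng.normal(size=(3, 10, 3))
        assert rmsd_after_fit(a, c) <= rmsd_after_fit(a, b) + rmsd_after_fit(b, c) + 1e-9

    def test_planted_coordinate_noise_matches_closed_form(self):
        # iid sigma per coordinate => RMSD ~ sigma*sqrt(3)
        rng = np.random.default_rng(7)
        sigma = 0.3
        base = rng.normal(size=(4000, 3)) * 10.0
        noisy = base + rng.normal(0.0, sigma, base.shape)
        assert rmsd_after_fit(base, noisy) == pytest.approx(
            sigma * np.sqrt(3.0), rel=0.05
        )

    def test_separate_fit_and_measure_subsets(self, rng):
        a = rng.normal(size=(10, 3))
        b = a.copy()
        b[5:] += 2.0  # uniformly displaced block, measured but not fitted
        fit = list(range(5))
        measure = list(range(5, 10))
        # fit aligns the identical half; the measured half keeps its
        # |(2,2,2)| displacement
        assert rmsd_after_fit(a, b, fit, measure) == pytest.approx(
            2.0 * np.sqrt(3.0), abs=1e-8
        )
        assert rmsd_after_fit(a, b, fit, fit) == pytest.approx(0.0, abs=1e-8)


class TestScalarMeasures:
    def test_two_point_radius_of_gyration(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(coords, np.ones(2)) == pytest.approx(1.0)

    def test_cube_radius_of_gyration(self):
        corners = np.array(
            [[x, y, z] for x in (0, 2.0) for y in (0, 2.0) for z in (0, 2.0)]
        )
        assert radius_of_gyration(corners, np.ones(8)) == pytest.approx(np.sqrt(3.0))

    def test_rg_rigid_invariance(self, rng):
        coords = rng.normal(size=(30, 3))
        masses = rng.uniform(1, 16, 30)
        rot, trans = random_rigid_transform(rng)
        assert radius_of_gyration(coords @ rot.T + trans, masses) == pytest.approx(
            radius_of_gyration(coords, masses), abs=1e-10
        )

    def test_center_of_mass_translation_equivariance(self, rng):
        coords = rng.normal(size=(5, 3))
        masses = rng.uniform(1, 12, 5)
        v = np.array([1.0, -2.0, 3.0])
        assert np.allclose(
            center_of_mass(coords + v, masses), center_of_mass(coords, masses) + v
        )

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            center_of_mass(np.zeros((2, 3)), np.zeros(2))


class TestEndToEndAndRings:
    def test_template_end_to_end_distance_is_exact(self, dimer_spec):
        spec = syn.ConformerTemplateSpec(
            kind="extended", sequence=syn.LINEAR_SEQUENCE, d_nc=10.0
        )
        topo, xyz = syn.build_template(spec)
        assert end_to_end_distance(xyz, topo, dimer_spec, "A") == pytest.approx(
            10.0, abs=1e-6
        )

    def test_simple_3_4_5_distance(self, dimer_spec, cyclic_template):
        topo, xyz = cyclic_template
        xyz = xyz.copy()
        # move terminus atoms to a known separation
        names = {(a.res_seq, a.name): i for i, a in enumerate(topo)}
        xyz[names[(59, "N")]] = [0.0, 0.0, 0.0]
        xyz[names[(71, "C")]] = [3.0, 4.0, 0.0]
        assert end_to_end_distance(xyz, topo, dimer_spec, "B") == pytest.approx(5.0)

    @pytest.mark.parametrize("angle", [0.0, 54.0, 90.0, 180.0])
    def test_ring_angle_inverts_planted_value(self, dimer_spec, angle):
        spec = syn.ConformerTemplateSpec(
            kind="extended", sequence=syn.LINEAR_SEQUENCE, ring_angle=angle
        )
        topo, xyz = syn.build_template(spec)
        assert ring_orientation_angle(xyz, topo, dimer_spec, "A") == pytest.approx(
            angle, abs=1e-6
        )

    def test_degenerate_ring_vector_rejected(self, dimer_spec, cyclic_template):
        topo, xyz = cyclic_template
        xyz = xyz.copy()
        names = {(a.res_seq, a.name): i for i, a in enumerate(topo)}
        xyz[names[(63, "CG")]] = xyz[names[(63, "CA")]]
        with pytest.raises(DegenerateGeometryError):
            ring_orientation_angle(xyz, topo, dimer_spec, "B")


class TestContacts:
    def test_two_single_atom_groups(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 4.2]])
        assert min_contact_distance(coords, [0], [1]) == pytest.approx(4.2)

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.normal(scale=8.0, size=(50, 3))
        ga, gb = list(range(20)), list(range(20, 50))
        assert min_contact_distance(coords, ga, gb) == pytest.approx(
            brute_min_distance(coords, ga, gb), abs=1e-12
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            min_contact_distance(np.zeros((2, 3)), [], [0])


class TestSasa:
    def test_isolated_atom_area_is_full_extended_sphere(self):
        r = 1.7
        res = shrake_rupley_sasa(np.zeros((1, 3)), np.array([r]))
        expect = 4.0 * np.pi * (r + 1.4) ** 2
        assert res.per_atom_area[0] == pytest.approx(expect, rel=2.0 / 960)

    def test_fully_buried_atom_has_zero_area(self):
        # central atom enclosed by a tight shell of neighbors
        shell = 2.0 * np.array(
            [
                [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
                [0.577, 0.577, 0.577], [-0.577, 0.577, 0.577],
                [0.577, -0.577, 0.577], [0.577, 0.577, -0.577],
                [-0.577, -0.577, 0.577], [-0.577, 0.577, -0.577],
                [0.577, -0.577, -0.577], [-0.577, -0.577, -0.577],
            ]
        )
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 1.7)
        res = shrake_rupley_sasa(coords, radii)
        assert res.per_atom_area[0] == 0.0

    def test_fully_overlapping_pair_totals_one_sphere(self):
        # near-coincident identical atoms: each exposes half its sphere,
        # the union is a single sphere
        coords = np.array([[0.0, 0.0, 0.0], [1e-3, 0.0, 0.0]])
        radii = np.array([1.5, 1.5])
        res = shrake_rupley_sasa(coords, radii)
        one_sphere = 4.0 * np.pi * (1.5 + 1.4) ** 2
        assert res.total_area == pytest.approx(one_sphere, rel=0.05)
        assert res.per_atom_area[0] == pytest.approx(one_sphere / 2, rel=0.1)

    def test_total_area_non_increasing_as_atoms_approach(self):
        radii = np.array([1.7, 1.52])
        areas = []
        for d in (8.0, 4.0, 3.0, 2.0, 1.0):
            coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
            areas.append(shrake_rupley_sasa(coords, radii).total_area)
        assert np.all(np.diff(areas) <= 1e-9)

    def test_point_density_convergence(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        radii = np.array([1.7, 1.7])
        coarse = shrake_rupley_sasa(coords, radii, n_points=960).total_area
        fine = shrake_rupley_sasa(coords, radii, n_points=4000).total_area
        assert coarse == pytest.approx(fine, rel=0.02)


class TestBuriedArea:
    def test_far_separated_chains_bury_nothing(self, dimer_spec):
        topo, xyz = syn.build_dimer_template(
            syn.ConformerTemplateSpec(kind="extended", sequence=syn.LINEAR_SEQUENCE),
            syn.default_cyclic_template(),
            translation=(0.0, 100.0, 0.0),
        )
        assert buried_hydrophobic_area(xyz, topo, dimer_spec) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_non_increasing_along_rigid_pull(self, dimer_spec):
        topo, xyz = syn.build_dimer_template(
            syn.ConformerTemplateSpec(
                kind="hairpin",
                sequence=syn.LINEAR_SEQUENCE,
                planted_hbonds=list(syn.LINEAR_LADDER_BONDS),
            ),
            syn.default_cyclic_template(),
            translation=(0.0, 10.0, 0.0),
        )
        pull = syn.rigid_pull_trajectory(
            topo, xyz, "B", direction=(0.0, 1.0, 0.0), offsets=[0.0, 3.0, 6.0, 30.0]
        )
        areas = [
            buried_hydrophobic_area(pull.coords[f], topo, dimer_spec)
            for f in range(pull.n_frames)
        ]
        assert areas[0] > 1.0  # chains in contact actually bury area
        assert np.all(np.diff(areas) <= 1e-6)

    def test_rigid_invariance_of_full_molecule_sasa(self, rng, cyclic_template):
        topo, xyz = cyclic_template
        radii = vdw_radii(topo)
        rot, trans = random_rigid_transform(rng)
        a = shrake_rupley_sasa(xyz, radii).total_area
        b = shrake_rupley_sasa(xyz @ rot.T + trans, radii).total_area
        assert a == pytest.approx(b, rel=0.01)
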
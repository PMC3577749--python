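import numpy as np
import pytest

from pepdimer import synthetic as syn
from pepdimer._tables import KB_KCAL_MOL_K
from pepdimer.errors import ConstructionError
from pepdimer.hbonds import HBondKey, detect_hbonds, existence_profile
from pepdimer.wham import UmbrellaWindow

KT300 = KB_KCAL_MOL_K * 300.0


class TestMetropolis:
    def test_unbiased_harmonic_variance_matches_boltzmann(self):
        kappa = 5.0
        chain = syn.metropolis_sample(
            syn.harmonic(kappa), n=50000, seed=0, thin=2
        )
        assert chain.samples.var() == pytest.approx(KT300 / kappa, rel=0.05)

    def test_bias_only_sampling_centers_on_the_window(self):
        w = UmbrellaWindow(center=1.7, k=20.0, samples=np.array([0.0]))
        flat = syn.Potential1D("flat", {}, lambda x: np.zeros_like(x))
        chain = syn.metropolis_sample(flat, bias=w, n=50000, seed=1, thin=2)
        assert chain.samples.mean() == pytest.approx(1.7, abs=0.01)
        assert chain.samples.var() == pytest.approx(KT300 / 20.0, rel=0.05)

    def test_same_seed_reproduces_the_chain_exactly(self):
        a = syn.metropolis_sample(syn.double_well(), n=500, seed=9)
        b = syn.metropolis_sample(syn.double_well(), n=500, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_acceptance_rate_within_mixing_bounds(self):
        chain = syn.metropolis_sample(syn.double_well(), n=5000, seed=3)
        assert 0.2 < chain.acceptance_rate < 0.8


class TestUmbrellaDataset:
    def test_default_geometry_has_26_windows_half_angstrom_apart(self):
        centers = syn.default_umbrella_centers()
        assert len(centers) == 26
        assert np.allclose(np.diff(centers), 0.5)
        windows, _ = syn.generate_umbrella_dataset(
            syn.double_well(), n_per_window=100, seed=0
        )
        assert len(windows) == 26
        assert all(w.k == 20.0 for w in windows)
        assert all(len(w.samples) == 100 for w in windows)

    def test_window_means_follow_the_centers(self):
        windows, _ = syn.generate_umbrella_dataset(
            syn.double_well(), n_per_window=500, seed=2
        )
        means = np.array([w.samples.mean() for w in windows])
        assert np.all(np.diff(means) > -0.1)  # non-decreasing up to noise

    def test_seed_determinism(self):
        w1, _ = syn.generate_umbrella_dataset(syn.double_well(), n_per_window=50, seed=7)
        w2, _ = syn.generate_umbrella_dataset(syn.double_well(), n_per_window=50, seed=7)
        for a, b in zip(w1, w2):
            assert np.array_equal(a.samples, b.samples)


class TestPotentials:
    def test_double_well_shape(self):
        u = syn.double_well()
        assert u(1.0) == 0.0 and u(-1.0) == 0.0
        assert u(0.0) == pytest.approx(2.0)

    def test_plateau_potential_is_exactly_flat_outside_width(self):
        u = syn.well_plus_plateau(depth=3.0, width=2.0, x0=2.0)
        assert u(2.0) == pytest.approx(-3.0)
        assert u(4.0) == 0.0 and u(9.0) == 0.0 and u(-1.0) == 0.0


class TestTemplateConstraints:
    def test_dnc_on_hairpin_conflicts_with_ladder(self):
        with pytest.raises(ConstructionError, match="d_nc"):
            syn.build_template(
                syn.ConformerTemplateSpec(
                    kind="hairpin", sequence=syn.LINEAR_SEQUENCE, d_nc=10.0
                )
            )

    def test_planted_bonds_on_extended_rejected(self):
        with pytest.raises(ConstructionError):
            syn.build_template(
                syn.ConformerTemplateSpec(
                    kind="extended",
                    sequence=syn.LINEAR_SEQUENCE,
                    planted_hbonds=[(70, 60)],
                )
            )

    def test_non_partner_planted_bond_rejected(self):
        with pytest.raises(ConstructionError, match="ladder partners"):
            syn.build_template(
                syn.ConformerTemplateSpec(
                    kind="hairpin",
                    sequence=syn.LINEAR_SEQUENCE,
                    planted_hbonds=[(70, 61)],
                )
            )

    def test_unreachable_dnc_rejected(self):
        with pytest.raises(ConstructionError, match="reachable"):
            syn.build_template(
                syn.ConformerTemplateSpec(
                    kind="extended", sequence=syn.LINEAR_SEQUENCE, d_nc=500.0
                )
            )

    def test_planted_keys_accepted_as_hbondkey(self):
        key = HBondKey("A", 60, "NH", "A", 70, "O")
        topo, xyz = syn.build_template(
            syn.ConformerTemplateSpec(
                kind="hairpin", sequence=syn.LINEAR_SEQUENCE, planted_hbonds=[key]
            )
        )
        assert key in detect_hbonds(xyz, topo, scope="A")


class TestEnsembles:
    def test_zero_noise_frames_equal_their_templates(self):
        recipe = syn.default_dimer_recipe(n_frames=20, noise_sigma=0.0, seed=4)
        traj, labels = syn.generate_ensemble(recipe)
        built = recipe.templates
        for f in range(traj.n_frames):
            assert np.array_equal(traj.coords[f], built[labels[f]][1])

    def test_label_counts_within_multinomial_bounds(self):
        recipe = syn.default_dimer_recipe(n_frames=1000, noise_sigma=0.0, seed=8)
        _, labels = syn.generate_ensemble(recipe)
        counts = np.bincount(labels, minlength=4)
        for count, w in zip(counts, (0.4, 0.3, 0.2, 0.1)):
            sd = np.sqrt(1000 * w * (1 - w))
            assert abs(count - 1000 * w) < 3.5 * sd  # ~99.95% bound

    def test_seed_determinism(self):
        r = syn.default_dimer_recipe(n_frames=15, noise_sigma=0.2, seed=5)
        t1, l1 = syn.generate_ensemble(r)
        t2, l2 = syn.generate_ensemble(r)
        assert np.array_equal(t1.coords, t2.coords) and np.array_equal(l1, l2)

    def test_mismatched_topologies_rejected(self):
        a = syn.build_template(
            syn.ConformerTemplateSpec(kind="extended", sequence=syn.LINEAR_SEQUENCE)
        )
        b = syn.build_template(syn.default_cyclic_template())
        with pytest.raises(ConstructionError, match="topology"):
            syn.generate_ensemble(
                syn.EnsembleRecipe(templates=[a, b], weights=(0.5, 0.5), n_frames=4)
            )

    def test_invalid_weights_rejected(self):
        a = syn.build_template(
            syn.ConformerTemplateSpec(kind="extended", sequence=syn.LINEAR_SEQUENCE)
        )
        with pytest.raises(ValueError):
            syn.EnsembleRecipe(templates=[a, a], weights=(0.5, 0.1), n_frames=4)


class TestSchedules:
    @pytest.fixture()
    def flat_traj(self, cyclic_template):
        from pepdimer.trajectory import Trajectory

        topo, xyz = cyclic_template
        return Trajectory(topology=topo, coords=np.repeat(xyz[None], 40, axis=0))

    @pytest.mark.parametrize("fraction", [0.0, 0.7, 1.0])
    def test_exact_count_persistence(self, flat_traj, fraction):
        key = HBondKey("B", 62, "NH", "B", 68, "O")
        traj = syn.schedule_hbond_presence(flat_traj, key, fraction, seed=3)
        profile = existence_profile(traj, scope="B")
        if fraction == 0.0:
            assert key not in profile.keys
        else:
            assert profile.persistence[profile.keys.index(key)] == pytest.approx(
                fraction, abs=1e-12
            )

    def test_out_of_range_fraction_rejected(self, flat_traj):
        key = HBondKey("B", 62, "NH", "B", 68, "O")
        with pytest.raises(ValueError):
            syn.schedule_hbond_presence(flat_traj, key, 1.2, seed=0)

    def test_other_bonds_untouched(self, flat_traj):
        key = HBondKey("B", 62, "NH", "B", 68, "O")
        traj = syn.schedule_hbond_presence(flat_traj, key, 0.5, seed=3)
        profile = existence_profile(traj, scope="B")
        others = [k for k in profile.keys if k != key]
        for k in others:
            assert profile.persistence[profile.keys.index(k)] == 1.0
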
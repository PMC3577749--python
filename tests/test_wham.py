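import numpy as np
import pytest

from pepdimer import synthetic as syn
from pepdimer._tables import KB_KCAL_MOL_K
from pepdimer.errors import WHAMError
from pepdimer.wham import (
    UmbrellaWindow,
    WHAMResult,
    bias_energy,
    binned_reference_pmf,
    contact_vs_com_profile,
    dissociation_delta_g,
    pmf_rms_error,
    read_window_metadata,
    wham_solve,
    write_windows,
)

KT300 = KB_KCAL_MOL_K * 300.0


class TestBias:
    def test_zero_at_center(self):
        w = UmbrellaWindow(center=3.0, k=20.0, samples=np.array([3.0]))
        assert bias_energy(w, 3.0) == 0.0

    def test_half_k_delta_squared(self):
        # k = 20 kcal/mol/A^2 at half the window spacing: 0.5*20*0.25
        w = UmbrellaWindow(center=3.0, k=20.0, samples=np.array([3.0]))
        assert bias_energy(w, 3.5) == pytest.approx(2.5)

    def test_symmetry_about_center(self):
        w = UmbrellaWindow(center=1.0, k=7.0, samples=np.array([1.0]))
        assert bias_energy(w, 1.0 + 0.3) == pytest.approx(bias_energy(w, 1.0 - 0.3))


class TestWhamLimits:
    def test_single_unbiased_window_reproduces_log_histogram(self, rng):
        samples = rng.normal(0.0, 0.8, 20000)
        w = UmbrellaWindow(center=0.0, k=1e-9, samples=samples)
        res = wham_solve([w], bin_width=0.1)
        counts, edges = np.histogram(samples, bins=np.arange(
            np.floor(samples.min() / 0.1) * 0.1,
            np.ceil(samples.max() / 0.1) * 0.1 + 0.05, 0.1))
        pop = counts > 0
        expect = -KT300 * np.log(counts[pop])
        expect -= expect.min()
        got = res.pmf[res.populated]
        assert np.allclose(got, expect, atol=1e-6)

    def test_duplicate_windows_match_single_window(self, rng):
        samples = rng.normal(1.0, 0.3, 5000)
        w1 = UmbrellaWindow(center=1.0, k=5.0, samples=samples)
        w2 = UmbrellaWindow(center=1.0, k=5.0, samples=samples.copy())
        res1 = wham_solve([w1])
        res2 = wham_solve([w1, w2])
        assert np.allclose(res1.pmf[res1.populated], res2.pmf[res2.populated], atol=1e-6)

    def test_window_permutation_invariance(self):
        windows, _ = syn.generate_umbrella_dataset(
            syn.harmonic(5.0), centers=np.arange(-2.0, 2.1, 0.5), n_per_window=800,
            seed=3,
        )
        res = wham_solve(windows)
        res_p = wham_solve(windows[::-1])
        assert np.allclose(res.pmf[res.populated], res_p.pmf[res_p.populated], atol=1e-8)

    def test_gauge_is_pinned_to_first_window(self):
        windows, _ = syn.generate_umbrella_dataset(
            syn.harmonic(5.0), centers=np.arange(-1.5, 1.6, 0.5), n_per_window=500,
            seed=4,
        )
        res = wham_solve(windows)
        assert res.f_i[0] == 0.0
        assert res.converged

    def test_splitting_a_window_leaves_pmf_unchanged(self, rng):
        samples = rng.normal(0.5, 0.25, 6000)
        whole = UmbrellaWindow(center=0.5, k=10.0, samples=samples)
        half_a = UmbrellaWindow(center=0.5, k=10.0, samples=samples[:3000])
        half_b = UmbrellaWindow(center=0.5, k=10.0, samples=samples[3000:])
        res1 = wham_solve([whole])
        res2 = wham_solve([half_a, half_b])
        assert np.allclose(res1.pmf[res1.populated], res2.pmf[res2.populated], atol=1e-6)

    def test_harmonic_curvature_recovered_within_ten_percent(self):
        kappa = 5.0
        windows, pot = syn.generate_umbrella_dataset(
            syn.harmonic(kappa), centers=np.arange(-2.0, 2.1, 0.5),
            n_per_window=5000, seed=11,
        )
        res = wham_solve(windows)
        mask = res.populated & (np.abs(res.bin_centers) <= 0.5)
        coef = np.polyfit(res.bin_centers[mask], res.pmf[mask], 2)
        assert 2.0 * coef[0] == pytest.approx(kappa, rel=0.10)

    def test_disjoint_islands_raise_naming_the_gap(self, rng):
        w1 = UmbrellaWindow(center=0.0, k=20.0, samples=rng.normal(0.0, 0.1, 500))
        w2 = UmbrellaWindow(center=5.0, k=20.0, samples=rng.normal(5.0, 0.1, 500))
        with pytest.raises(WHAMError, match="island"):
            wham_solve([w1, w2])

    def test_unconverged_run_is_flagged_not_raised(self):
        windows, _ = syn.generate_umbrella_dataset(
            syn.harmonic(5.0), centers=np.arange(-1.0, 1.1, 0.5), n_per_window=300,
            seed=5,
        )
        res = wham_solve(windows, max_iter=2)
        assert not res.converged


class TestDissociation:
    def _result_from(self, centers, pmf):
        return WHAMResult(
            bin_centers=centers,
            pmf=pmf,
            f_i=np.zeros(2),
            n_samples=np.full(len(centers), 1000.0),
            n_iter=1,
            converged=True,
            temperature=300.0,
        )

    def test_constructed_well_plus_flat_gives_depth(self):
        # well bottom at c=2 (pmf 0), flat plateau at 3 beyond c=4
        c = np.arange(0.0, 10.0, 0.05)
        pmf = np.where(
            c < 4.0, 3.0 * np.clip((c - 2.0) / 2.0, -1.0, 1.0) ** 2, 3.0
        )
        est = dissociation_delta_g(self._result_from(c, pmf))
        assert est.delta_g == pytest.approx(3.0, abs=0.01)
        assert est.min_location == pytest.approx(2.0, abs=0.05)

    def test_monotone_ramp_has_no_plateau(self):
        c = np.arange(0.0, 10.0, 0.05)
        with pytest.raises(WHAMError, match="plateau"):
            dissociation_delta_g(self._result_from(c, 0.5 * c))

    def test_sampled_well_recovers_depth_within_two_tenths(self):
        pot = syn.well_plus_plateau(depth=3.0, width=2.0, x0=2.0)
        windows, _ = syn.generate_umbrella_dataset(
            pot, centers=np.arange(0.0, 13.0, 0.5), n_per_window=5000, seed=2,
            thin=10,
        )
        res = wham_solve(windows)
        est = dissociation_delta_g(res, slope_tol=0.1)
        assert est.delta_g == pytest.approx(3.0, abs=0.2)
        assert est.min_location == pytest.approx(2.0, abs=0.3)


class TestRecoveryScoring:
    def test_rms_error_is_offset_invariant(self):
        c = np.arange(-1.0, 1.01, 0.05)
        pmf = 0.5 * 5.0 * c**2
        res = WHAMResult(
            bin_centers=c, pmf=pmf + 7.3, f_i=np.zeros(1),
            n_samples=np.full(len(c), 100.0), n_iter=1, converged=True,
            temperature=300.0,
        )
        ref = binned_reference_pmf(syn.harmonic(5.0))
        assert pmf_rms_error(res, ref) < 0.01


class TestContactProfile:
    def test_rigid_pull_gives_increasing_contact_distance(self, dimer_spec):
        topo, xyz = syn.build_dimer_template(
            syn.ConformerTemplateSpec(
                kind="hairpin",
                sequence=syn.LINEAR_SEQUENCE,
                planted_hbonds=list(syn.LINEAR_LADDER_BONDS),
            ),
            syn.default_cyclic_template(),
            translation=(0.0, 10.0, 0.0),
        )
        offsets = np.arange(0.0, 20.0, 1.0)
        pull = syn.rigid_pull_trajectory(topo, xyz, "B", (0.0, 1.0, 0.0), offsets)
        df = contact_vs_com_profile(pull, dimer_spec)
        assert len(df) == pull.n_frames
        assert np.all(np.diff(df["com_separation_A"]) > 0)
        assert np.all(np.diff(df["min_contact_A"]) > 0)
        assert df["moving_avg_A"].notna().all()

    def test_coincident_ring_atoms_give_zero_contact(self, dimer_spec):
        topo, xyz = syn.build_dimer_template(
            syn.ConformerTemplateSpec(kind="extended", sequence=syn.LINEAR_SEQUENCE),
            syn.default_cyclic_template(),
            translation=(0.0, 30.0, 0.0),
        )
        names = {
            (a.chain_id, a.res_seq, a.name): i for i, a in enumerate(topo)
        }
        shift = xyz[names[("A", 63, "CG")]] - xyz[names[("B", 63, "CG")]]
        mask = np.array([a.chain_id == "B" for a in topo])
        moved = xyz.copy()
        moved[mask] += shift
        traj = syn.rigid_pull_trajectory(topo, moved, "B", (0, 0, 1.0), [0.0])
        df = contact_vs_com_profile(traj, dimer_spec)
        assert df["min_contact_A"].iloc[0] == pytest.approx(0.0, abs=1e-9)


class TestWindowIO:
    def test_round_trip(self, tmp_path, rng):
        windows = [
            UmbrellaWindow(center=c, k=20.0, samples=rng.normal(c, 0.2, 50))
            for c in (0.0, 0.5, 1.0)
        ]
        meta = write_windows(windows, tmp_path)
        back = read_window_metadata(meta)
        assert len(back) == 3
        for w, b in zip(windows, back):
            assert b.center == w.center and b.k == w.k
            assert np.allclose(b.samples, w.samples, atol=1e-6)

    def test_missing_columns_rejected(self, tmp_path):
        bad = tmp_path / "meta.csv"
        bad.write_text("label,center_A\nw0,0.0\n")
        with pytest.raises(WHAMError, match="missing columns"):
            read_window_metadata(bad)

    def test_malformed_row_names_the_row(self, tmp_path):
        bad = tmp_path / "meta.csv"
        bad.write_text(
            "label,center_A,k_kcal_mol_A2,samples_path\nw0,0.0,20.0,missing.dat\n"
        )
        with pytest.raises(WHAMError, match="row 0"):
            read_window_metadata(bad)
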
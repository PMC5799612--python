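"""Brownian-dynamics generator: physics checks and reproducibility."""

import numpy as np
import pytest
from scipy.stats import kstest

import memperm as mp
from memperm.constants import kt
from memperm.synthetic import _simulate_batch


class TestSimulateWindow:
    def test_same_seed_bit_identical(self):
        spec = mp.LandscapeSpec(form="flat")
        a = mp.simulate_window(spec, (0.0, 2.5), dt=0.05, n_steps=5000, seed=9)
        b = mp.simulate_window(spec, (0.0, 2.5), dt=0.05, n_steps=5000, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_different_seed_differs(self):
        spec = mp.LandscapeSpec(form="flat")
        a = mp.simulate_window(spec, (0.0, 2.5), dt=0.05, n_steps=5000, seed=9)
        b = mp.simulate_window(spec, (0.0, 2.5), dt=0.05, n_steps=5000, seed=10)
        assert not np.array_equal(a.positions, b.positions)

    def test_free_diffusion_msd(self):
        # many replicas on a flat landscape: MSD(t) = 2Dt within 5 %
        spec = mp.LandscapeSpec(form="flat", D_bulk=0.1, D_core=0.1)
        rng = np.random.default_rng(30)
        pos = _simulate_batch(spec, np.zeros(5000), None, 0.0, dt=0.05,
                              n_steps=10_000, save_stride=20, rng=rng)
        t = 1.0 * (1 + np.arange(pos.shape[1]))
        msd = (pos**2).mean(axis=0)
        for t_check in (100.0, 250.0, 500.0):
            i = np.argmin(np.abs(t - t_check))
            assert msd[i] / (2 * 0.1 * t[i]) == pytest.approx(1.0, abs=0.05)

    def test_equipartition_variance(self):
        # harmonic total potential: var(z) = k_BT / k within 3 %
        spec = mp.LandscapeSpec(form="flat")
        rng = np.random.default_rng(31)
        pos = _simulate_batch(spec, np.zeros(50), np.zeros(50), 2.5, dt=0.05,
                              n_steps=100_000, save_stride=20, rng=rng, burn_in=2000)
        var = pos.var()
        assert var == pytest.approx(kt(310.0) / 2.5, rel=0.03)

    def test_constant_tilt_shifts_stationary_mean(self):
        # tilt force t against spring k: stationary mean moves to t/k
        spec = mp.LandscapeSpec(form="flat", tilt=0.2)
        rng = np.random.default_rng(34)
        pos = _simulate_batch(spec, np.zeros(20), np.zeros(20), 2.5, dt=0.05,
                              n_steps=50_000, save_stride=20, rng=rng,
                              burn_in=2000)
        assert pos.mean() == pytest.approx(0.2 / 2.5, abs=0.01)

    def test_dt_precondition_suggests_value(self):
        spec = mp.LandscapeSpec(form="flat")
        with pytest.raises(ValueError, match="use dt <"):
            mp.simulate_window(spec, (0.0, 250.0), dt=0.5, n_steps=100, seed=1)


class TestDetailedBalance:
    def test_boltzmann_stationary_distribution(self):
        # harmonically confined walkers: stationary law is exp(−W_tot/kT),
        # i.e. Gaussian with σ² = k_BT/k; KS on decorrelated samples
        spec = mp.LandscapeSpec(form="flat")
        k = 2.5  # relaxation time k_BT/(kD) ≈ 2.5 ps = 50 steps
        rng = np.random.default_rng(32)
        pos = _simulate_batch(spec, np.zeros(5), np.zeros(5), k, dt=0.05,
                              n_steps=200_000, save_stride=200, rng=rng,
                              burn_in=2_000)
        sigma = np.sqrt(kt(310.0) / k)
        samples = pos.ravel()  # spacing 10 ps ≈ 4 relaxation times
        stat, p = kstest(samples / sigma, "norm")
        assert p > 0.01

    def test_without_spurious_drift_distribution_skews(self):
        # dropping D′(z) leaves a stationary density ∝ exp(−W/kT)/D(z):
        # the slow-D core becomes overpopulated
        spec = mp.LandscapeSpec(form="flat", D_bulk=0.1, D_core=0.01,
                                d_switch_z=0.5, d_switch_width=0.3)
        k = 0.1
        sigma2 = kt(310.0) / k

        def core_fraction(drift):
            rng = np.random.default_rng(33)
            pos = _simulate_batch(spec, np.zeros(20), np.zeros(20), k, dt=0.02,
                                  n_steps=150_000, save_stride=100, rng=rng,
                                  burn_in=20_000, spurious_drift=drift)
            return np.mean(np.abs(pos) < 0.5)

        from scipy.stats import norm
        expected = norm.cdf(0.5 / np.sqrt(sigma2)) - norm.cdf(-0.5 / np.sqrt(sigma2))
        with_drift = core_fraction(True)
        without = core_fraction(False)
        assert with_drift == pytest.approx(expected, rel=0.15)
        assert without > 1.5 * expected  # strongly overweighted core


class TestGenerateDataset:
    def test_writes_consumable_dataset(self, tmp_path):
        landscape = mp.LandscapeSpec(form="flat")
        centers = np.arange(-2.0, 3.0, 1.0)
        out = str(tmp_path / "run")
        ds, truth_w, truth_d = mp.generate_dataset(
            landscape, centers=centers, n_steps=20_000, base_seed=40, out_dir=out
        )
        back = mp.read_metadata(out + "/metadata.dat", equilibration_discard=0.0)
        assert len(back.windows) == centers.size
        np.testing.assert_allclose(back.centers, centers)
        loaded = back.loaded()
        np.testing.assert_allclose(
            loaded.windows[0].series, ds.windows[0].series, atol=1e-7
        )
        truth_back = mp.read_profile(out + "/truth_pmf.dat")
        np.testing.assert_allclose(truth_back.values, truth_w.values, atol=1e-9)

    def test_window_seeds_reproduce_independently(self):
        landscape = mp.LandscapeSpec(form="flat")
        ds, _, _ = mp.generate_dataset(landscape, centers=np.array([-1.0, 4.0]),
                                       n_steps=5000, base_seed=50, burn_in=100)
        solo = mp.simulate_window(landscape, (4.0, 2.5), dt=0.05, n_steps=5000,
                                  seed=51, burn_in=100)
        np.testing.assert_array_equal(ds.windows[1].series, solo.positions)

    def test_centers_outside_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            mp.generate_dataset(mp.LandscapeSpec(form="flat", extent=10.0),
                                centers=np.array([0.0, 20.0]), n_steps=100)


class TestMembraneLandscape:
    def test_shape_constants(self):
        land = mp.membrane_landscape()
        assert land.energy(np.array([0.0]))[0] == pytest.approx(5.4, abs=0.01)
        assert land.energy(np.array([14.0]))[0] == pytest.approx(-2.8, abs=0.02)
        assert land.energy(np.array([40.0]))[0] == pytest.approx(0.0, abs=1e-6)
        assert land.diffusivity(np.array([0.0]))[0] == pytest.approx(0.01, rel=1e-2)
        assert land.diffusivity(np.array([40.0]))[0] == pytest.approx(0.1, rel=1e-3)

    def test_even_in_z(self):
        land = mp.membrane_landscape()
        z = np.linspace(0, 45, 200)
        np.testing.assert_allclose(land.energy(z), land.energy(-z), atol=1e-12)
        np.testing.assert_allclose(land.diffusivity(z), land.diffusivity(-z), atol=1e-12)


class TestSampleOrientations:
    def test_isotropic(self):
        theta = mp.sample_orientations(0.0, 200_000, seed=60)
        s = 0.5 * (3 * np.mean(np.cos(theta) ** 2) - 1)
        assert abs(s) < 0.01
        assert np.degrees(np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta)))) \
            == pytest.approx(90.0, abs=0.5)

    def test_strong_alignment_limit(self):
        # exact moments of the density ∝ e^{λu}: ⟨u⟩ = coth λ − 1/λ,
        # ⟨u²⟩ = 1 − 2⟨u⟩/λ, so S(λ=100) = 0.9703; S → 1 as λ grows
        for lam, seed in ((100.0, 61), (1000.0, 62)):
            theta = mp.sample_orientations(lam, 100_000, seed=seed)
            s = 0.5 * (3 * np.mean(np.cos(theta) ** 2) - 1)
            u_mean = 1.0 / np.tanh(lam) - 1.0 / lam
            s_exact = 0.5 * (3 * (1 - 2 * u_mean / lam) - 1)
            assert s == pytest.approx(s_exact, abs=0.002)
        assert s > 0.99  # λ = 1000 is within 1 % of perfect alignment

    def test_reproducible(self):
        a = mp.sample_orientations(2.0, 1000, seed=62)
        b = mp.sample_orientations(2.0, 1000, seed=62)
        np.testing.assert_array_equal(a, b)


class TestBuildFrames:
    def test_planted_zero_gives_zeros(self):
        frames = mp.build_frames(3, {"water": 10}, {"water": 0}, (30, 30, 30), seed=70)
        assert (mp.solvation_numbers(frames).counts == 0).all()

    def test_planting_across_periodic_wall(self):
        # solute near the box corner: the contact shell wraps the boundary
        frames = mp.build_frames(3, {"water": 10}, {"water": 3}, (26.0, 26.0, 26.0),
                                 seed=71, solute_center=(0.5, 0.5, 0.5))
        counts = mp.solvation_numbers(frames, cutoff=4.25)
        assert (counts.counts[:, 0] == 3).all()

    def test_overfull_shell_rejected(self):
        with pytest.raises(ValueError, match="cannot plant"):
            mp.build_frames(1, {"water": 2}, {"water": 5}, (30, 30, 30), seed=72)
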
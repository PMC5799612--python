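"""PMF post-processing: symmetry, anchoring, features, K, pKa, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memperm as mp
from memperm.constants import LN10, kt


def profile(z, w, **kw):
    return mp.Profile(np.asarray(z, float), np.asarray(w, float), **kw)


class TestSymmetrize:
    def test_symmetric_pmf_unchanged(self):
        z = np.linspace(-10, 10, 41)
        p = mp.symmetrize(profile(z, z**2))
        np.testing.assert_allclose(p.values, z**2, atol=1e-12)
        np.testing.assert_allclose(p.errors, 0.0, atol=1e-12)

    def test_odd_pmf_symmetrizes_to_zero(self):
        z = np.linspace(-1, 1, 21)
        p = mp.symmetrize(profile(z, z))
        np.testing.assert_allclose(p.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(p.errors, np.abs(z), atol=1e-12)

    def test_matches_pointwise_oracle_on_random_pmf(self):
        rng = np.random.default_rng(8)
        z = np.linspace(-8, 8, 33)  # symmetric grid: the oracle is exact
        w = rng.normal(size=z.size)
        p = mp.symmetrize(profile(z, w))
        w_rev = w[::-1]
        np.testing.assert_allclose(p.values, 0.5 * (w + w_rev), atol=1e-12)
        np.testing.assert_allclose(p.errors, 0.5 * np.abs(w - w_rev), atol=1e-12)

    def test_one_signed_grid_rejected(self):
        with pytest.raises(ValueError):
            mp.symmetrize(profile([1.0, 2.0, 3.0], [0, 0, 0]))

    def test_undefined_mirror_stays_undefined(self):
        z = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        w = np.array([np.nan, 1.0, 0.0, 1.0, 4.0])
        p = mp.symmetrize(profile(z, w))
        assert not p.defined_mask[0] and not p.defined_mask[-1]
        assert p.defined_mask[1] and p.defined_mask[3]


class TestAnchorBulk:
    def test_already_anchored_unchanged(self):
        z = np.linspace(-40, 40, 81)
        w = np.where(np.abs(z) >= 30, 0.0, 5.0)
        p = mp.anchor_bulk(profile(z, w))
        np.testing.assert_allclose(p.values, w, atol=1e-12)

    def test_gauge_invariance(self):
        z = np.linspace(-40, 40, 81)
        w = np.exp(-(z / 10) ** 2)
        a = mp.anchor_bulk(profile(z, w))
        b = mp.anchor_bulk(profile(z, w + 7.0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_asymmetric_plateaus_shift_by_mean(self):
        z = np.linspace(-40, 40, 161)
        w = np.where(z <= -30, 0.0, np.where(z >= 30, 0.4, 2.0))
        p = mp.anchor_bulk(profile(z, w))
        assert p.values[0] == pytest.approx(-0.2)
        assert p.values[-1] == pytest.approx(0.2)

    def test_no_bulk_points_rejected(self):
        with pytest.raises(ValueError, match="no defined"):
            mp.anchor_bulk(profile(np.linspace(-5, 5, 11), np.zeros(11)))


class TestExtractFeatures:
    @pytest.mark.parametrize(
        "w_peak, w_well, expected_barrier",
        [(14.38, -0.16, 14.54), (5.43, -2.79, 8.22)],
    )
    def test_barrier_heights_from_peak_and_well(self, w_peak, w_well, expected_barrier):
        z = np.linspace(-40, 40, 321)
        w = w_peak * np.exp(-(z**2) / 8.0) + w_well * (
            np.exp(-((z - 14) ** 2) / 8.0) + np.exp(-((z + 14) ** 2) / 8.0)
        )
        f = mp.extract_features(profile(z, w))
        assert f.w_peak == pytest.approx(w_peak, abs=1e-3)
        assert f.w_well == pytest.approx(w_well, abs=1e-3)
        assert f.w_barrier == pytest.approx(expected_barrier, abs=2e-3)
        assert f.z_peak == pytest.approx(0.0, abs=0.3)
        assert abs(f.z_well) == pytest.approx(14.0, abs=0.3)

    def test_flat_pmf_zero_barrier(self):
        f = mp.extract_features(profile(np.linspace(-40, 40, 81), np.zeros(81)))
        assert f.w_barrier == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_barrier_identity_bit_exact(self, seed):
        rng = np.random.default_rng(seed)
        z = np.linspace(-40, 40, 81)
        f = mp.extract_features(profile(z, rng.normal(size=z.size)))
        assert f.w_barrier == f.w_peak - f.w_well


class TestPartitionCoefficient:
    def test_flat_pmf_gives_unity_for_any_bounds(self):
        z = np.linspace(-40, 40, 161)
        p = profile(z, np.zeros_like(z))
        for z1, z2 in [(-40, 40), (-30, 10), (-12.5, 37.5)]:
            r = mp.partition_coefficient(p, z1, z2)
            assert r.K == pytest.approx(1.0, abs=1e-9)
            assert r.dG == pytest.approx(0.0, abs=1e-9)

    def test_smoothed_well_matches_fine_grid_quadrature(self):
        # 2 kcal/mol well over ~10 Å with smooth (tanh) edges so both
        # quadratures converge; agreement at 1e-6 relative
        kT = kt(310.0)

        def well(z):
            return -2.0 * 0.5 * (np.tanh(z + 5.0) - np.tanh(z - 5.0))

        z = np.linspace(-40, 40, 80_001)
        r = mp.partition_coefficient(profile(z, well(z)), -40, 40, 310.0)
        zf = np.linspace(-40, 40, 800_001)
        k_ref = np.trapezoid(np.exp(-well(zf) / kT), zf) / 80.0
        assert r.K == pytest.approx(k_ref, rel=1e-6)

    def test_k_dg_consistency_and_table_values(self):
        # Eq.-4 arm standalone: K = 13.41 at 310 K corresponds to −1.60 kcal/mol
        assert mp.dG_from_K(13.41, 310.0) == pytest.approx(-1.60, abs=0.005)
        assert mp.dG_from_K(0.69, 310.0) == pytest.approx(0.23, abs=0.005)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_exp_minus_dg_recovers_k(self, seed):
        rng = np.random.default_rng(seed)
        z = np.linspace(-40, 40, 161)
        w = np.cumsum(rng.normal(scale=0.1, size=z.size))
        w -= w[0]
        r = mp.partition_coefficient(profile(z, w), -40, 40, 310.0)
        assert np.exp(-r.dG / kt(310.0)) == pytest.approx(r.K, rel=1e-9)

    def test_undefined_gap_rejected(self):
        z = np.linspace(-40, 40, 81)
        w = np.zeros_like(z)
        w[40] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            mp.partition_coefficient(profile(z, w), -40, 40)

    def test_reference_side_options(self):
        z = np.linspace(-40, 40, 161)
        w = np.where(z < 0, 0.0, 1.0)  # offset plateaus
        k_left = mp.partition_coefficient(profile(z, w), -40, 40, reference="left").K
        k_right = mp.partition_coefficient(profile(z, w), -40, 40, reference="right").K
        k_mean = mp.partition_coefficient(profile(z, w), -40, 40, reference="mean").K
        assert k_left < k_mean < k_right


class TestPkaShift:
    def test_identical_pmfs_give_zero(self):
        z = np.linspace(-40, 40, 81)
        w = np.exp(-(z / 10) ** 2)
        p = mp.pka_shift_profile(profile(z, w), profile(z, w))
        np.testing.assert_allclose(p.values, 0.0, atol=1e-12)

    def test_peak_value_from_table_numbers(self):
        # neutral peak 5.43, charged peak 14.38 → shift ≈ −6.31 at 310 K
        z = np.linspace(-40, 40, 161)
        wn = 5.43 * np.exp(-(z**2) / 8.0)
        wc = 14.38 * np.exp(-(z**2) / 8.0)
        p = mp.pka_shift_profile(profile(z, wn), profile(z, wc), 310.0)
        i0 = np.argmin(np.abs(p.z_grid))
        expected = (5.43 - 14.38) / (LN10 * kt(310.0))
        assert p.values[i0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(-6.31, abs=0.01)

    def test_unit_shift_calibration(self):
        # ΔW of +1.419 kcal/mol at 310 K is one full pKa unit
        z = np.linspace(-1, 1, 11)
        p = mp.pka_shift_profile(
            profile(z, np.full(z.size, 1.419)), profile(z, np.zeros(z.size)), 310.0
        )
        np.testing.assert_allclose(p.values, 1.0, atol=1e-3)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(9)
        z = np.linspace(-40, 40, 81)
        wn, wc = rng.normal(size=z.size), rng.normal(size=z.size)
        a = mp.pka_shift_profile(profile(z, wn), profile(z, wc))
        b = mp.pka_shift_profile(profile(z, wc), profile(z, wn))
        np.testing.assert_allclose(a.values, -b.values, atol=1e-12)

    def test_disjoint_grids_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            mp.pka_shift_profile(
                profile([-2.0, -1.0], [0, 0]), profile([1.0, 2.0], [0, 0])
            )


class TestBoltzmannInvert:
    def test_uniform_samples_flat_profile(self):
        rng = np.random.default_rng(10)
        p = mp.boltzmann_invert(rng.uniform(-10, 10, 100_000), bin_width=1.0)
        inner = p.defined_mask.copy()
        inner[0] = inner[-1] = False  # edge bins are half-filled
        w = p.values[inner]
        assert np.all(np.abs(w - w.mean()) < 3.0 * p.errors[inner])

    def test_recovers_generating_landscape(self):
        # samples from exp(−W*/kT) with W* = ½z² are Gaussian with σ² = kT
        kT = kt(310.0)
        rng = np.random.default_rng(11)
        samples = rng.normal(scale=np.sqrt(kT), size=1_000_000)
        p = mp.boltzmann_invert(samples, 310.0, bin_width=0.05, z_range=(-2.0, 2.0))
        sel = p.defined_mask & (np.abs(p.z_grid) < 1.5)
        truth = 0.5 * p.z_grid[sel] ** 2
        w = p.values[sel]
        shift = np.mean(w - truth)
        assert np.sqrt(np.mean((w - truth - shift) ** 2)) < 0.1

    def test_empty_central_region_masked(self):
        rng = np.random.default_rng(12)
        samples = np.concatenate([rng.uniform(-10, -5, 5000), rng.uniform(5, 10, 5000)])
        p = mp.boltzmann_invert(samples, bin_width=1.0)
        central = np.abs(p.z_grid) < 4.0
        assert not p.defined_mask[central].any()
        assert np.isnan(p.values[central]).all()

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            mp.boltzmann_invert(np.full(100, 3.14))
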
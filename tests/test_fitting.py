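"""Decay binning and bi-/mono-exponential lifetime recovery."""

import numpy as np
import pytest

import flimcyte as fc
from flimcyte.decay import IRF, bin_centers
from flimcyte.fitting import _ShapeCache, _fit_mono_mle
from flimcyte.synthetic import TCSPCStack

from conftest import brute_force_bin


def make_stack(data_yxT, channel="NADH"):
    channels = ("NADH", "FAD", "mCherry")
    full = np.zeros((3,) + data_yxT.shape, dtype=data_yxT.dtype)
    full[channels.index(channel)] = data_yxT
    return TCSPCStack(data=full, channels=channels)


class TestBinDecays:
    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 50, size=(6, 6, 16), dtype=np.int64)
        stack = make_stack(data)
        assert np.array_equal(fc.bin_decays(stack, "NADH", kernel=1), data)

    def test_uniform_interior_scales_by_nine(self):
        data = np.full((5, 5, 8), 3, dtype=np.int64)
        binned = fc.bin_decays(make_stack(data), "NADH", kernel=3)
        assert np.array_equal(binned[2, 2], data[2, 2] * 9)

    def test_matches_brute_force_neighborhood_sum(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 100, size=(5, 5, 12), dtype=np.int64)
        binned = fc.bin_decays(make_stack(data), "NADH", kernel=3)
        assert np.array_equal(binned, brute_force_bin(data, 3))

    def test_even_kernel_rejected(self, small_scene):
        _, stack, _, _ = small_scene
        with pytest.raises(ValueError, match="odd"):
            fc.bin_decays(stack, "NADH", kernel=2)


class TestMeanLifetime:
    @pytest.mark.parametrize(
        "tau1,tau2,alpha1,expected",
        [(0.5, 2.5, 0.7, 1.1), (1.0, 3.0, 1.0, 1.0), (2.0, 2.0, 0.3, 2.0)],
    )
    def test_direct_formula(self, tau1, tau2, alpha1, expected):
        assert fc.mean_lifetime(tau1, tau2, alpha1) == pytest.approx(expected)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            fc.mean_lifetime(0.5, 2.5, 1.2)


class TestFitBiexponential:
    def test_parameter_recovery_at_high_photons(self, irf):
        h = fc.synthesize_decay(0.4, 2.5, 0.7, 0.5, irf, 1e5, rng=42)
        fit = fc.fit_biexponential(h, irf, 12.5, init=(0.5, 2.0, 0.6))
        assert fit.fitted and fit.converged
        assert fit.tau1 == pytest.approx(0.4, rel=0.10)
        assert fit.tau2 == pytest.approx(2.5, rel=0.10)
        assert fit.alpha1 == pytest.approx(0.7, abs=0.05)

    def test_mono_exponential_degeneracy_taum_identifiable(self, irf):
        """A single-exponential decay leaves the split ill-defined but the
        amplitude-weighted mean lifetime is still recovered."""
        h = fc.synthesize_decay(1.0, 3.0, 1.0, 0.0, irf, 1e5, rng=8)
        fit = fc.fit_biexponential(h, irf, 12.5)
        assert fit.tau_m == pytest.approx(1.0, rel=0.05)

    def test_all_zero_histogram_flagged_not_fitted(self, irf):
        fit = fc.fit_biexponential(np.zeros(irf.n_bins), irf, 12.5)
        assert not fit.fitted
        assert np.isnan(fit.tau_m)

    @pytest.mark.parametrize("seed", range(6))
    def test_invariants_ordering_and_weights(self, irf, seed):
        rng = np.random.default_rng(seed)
        tau1 = rng.uniform(0.2, 0.8)
        tau2 = rng.uniform(1.8, 4.0)
        a1 = rng.uniform(0.2, 0.9)
        h = fc.synthesize_decay(tau1, tau2, a1, 0.3, irf, 3e4, rng=rng)
        fit = fc.fit_biexponential(h, irf, 12.5)
        assert fit.tau1 < fit.tau2
        assert fit.tau1 <= fit.tau_m <= fit.tau2
        assert fit.alpha1 + fit.alpha2 == pytest.approx(1.0, abs=1e-9)
        assert fit.offset >= 0

    def test_error_shrinks_with_photon_budget(self, irf):
        """Mean |tau_m error| over 20 seeds decreases 1e3 -> 1e4 -> 1e5."""
        true = dict(tau1=0.4, tau2=2.5, alpha1=0.7)
        true_taum = fc.mean_lifetime(**true)
        errs = []
        for photons in (1e3, 1e4, 1e5):
            e = []
            for seed in range(20):
                h = fc.synthesize_decay(
                    true["tau1"], true["tau2"], true["alpha1"], 0.0, irf, photons,
                    rng=1000 + seed,
                )
                fit = fc.fit_biexponential(h, irf, 12.5)
                e.append(abs(fit.tau_m - true_taum))
            errs.append(np.mean(e))
        assert errs[0] > errs[1] > errs[2]

    def test_delta_irf_noiseless_fit_matches_analytic_curve(self):
        """With a delta IRF and no offset, the converged model evaluated at
        bin centers reproduces the analytic wrapped bi-exponential."""
        n_bins, period = 256, 12.5
        delta = IRF(histogram=np.eye(n_bins)[0], bin_width=period / n_bins)
        t = bin_centers(n_bins, period)
        tau1, tau2, a1 = 0.5, 2.2, 0.6
        curve = a1 * np.exp(-t / tau1) / (1 - np.exp(-period / tau1)) + (
            1 - a1
        ) * np.exp(-t / tau2) / (1 - np.exp(-period / tau2))
        y = 1e5 * curve / curve.sum()  # expectation, no Poisson noise
        fit = fc.fit_biexponential(y, delta, period)
        cache = _ShapeCache(delta, n_bins, period)
        model = fit.amplitude * cache.biexp(fit.tau1, fit.tau2, fit.alpha1) + fit.offset
        assert np.allclose(model, y, rtol=1e-3, atol=1e-2 * y.max())


class TestFitChannel:
    def test_fit_mask_covers_cells_not_dim_background(self):
        preset = fc.make_preset(
            "tumor", n_cells=3, field_size=(72, 72), seed=13,
            photons_per_pixel_background=20,  # below threshold even after 3x3 binning
        )
        stack, gt, irf = fc.render_scene(preset)
        img = fc.fit_channel(stack, "NADH", irf)
        cells = gt.label_image > 0
        assert np.all(img.fit_mask[cells])
        # pixels far from any cell stay unfitted
        from scipy.ndimage import binary_dilation
        halo = binary_dilation(cells, iterations=2)
        assert not img.fit_mask[~halo].any()

    def test_per_cell_taum_recovery(self, small_scene):
        _, stack, gt, irf = small_scene
        img = fc.fit_channel(stack, "NADH", irf, mask=gt.label_image > 0)
        for row in gt.per_cell.itertuples(index=False):
            true_taum = fc.mean_lifetime(
                row.true_nadh_tau1, row.true_nadh_tau2, row.true_nadh_alpha1
            )
            fitted = img["tau_m"][gt.label_image == row.cell_id]
            assert np.nanmean(fitted) == pytest.approx(true_taum, rel=0.10)

    def test_missing_channel_rejected(self, small_scene):
        _, stack, _, irf = small_scene
        with pytest.raises(KeyError):
            fc.fit_channel(stack, "GFP", irf)


class TestMcherryLifetime:
    def test_recovery_within_reporter_window(self, irf):
        h = fc.synthesize_decay(1.4, 2.8, 1.0, 0.2, irf, 1e4, rng=5)
        cache = _ShapeCache(irf, irf.n_bins, 12.5)
        tau = _fit_mono_mle(h.astype(float), cache)
        assert 1.3 <= tau <= 1.5

    def test_short_lifetime_falls_below_window(self, irf):
        h = fc.synthesize_decay(0.5, 2.8, 1.0, 0.0, irf, 1e4, rng=6)
        cache = _ShapeCache(irf, irf.n_bins, 12.5)
        assert _fit_mono_mle(h.astype(float), cache) < 1.3

    def test_background_pixels_absent(self, small_scene):
        _, stack, gt, irf = small_scene
        tau_img = fc.estimate_mcherry_lifetime(stack, irf)
        from scipy.ndimage import binary_dilation
        far = ~binary_dilation(gt.label_image > 0, iterations=3)
        assert np.all(np.isnan(tau_img[far]))
        assert np.all(np.isfinite(tau_img[gt.label_image > 0]))
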
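"""Synthetic TCSPC scene generator: presets, placement, decay synthesis."""

import numpy as np
import pytest

import flimcyte as fc
from flimcyte.decay import IRF, bin_centers
from flimcyte.synthetic import PHENOTYPES


class TestPresets:
    def test_tumor_preset_population_parameters(self):
        p = fc.make_preset("tumor")
        assert p.rr_mean == pytest.approx(2.567)
        assert p.rr_cv == pytest.approx(30.37)
        assert p.layout == "random"
        assert p.phenotype_probs["CD206+"] == pytest.approx(0.522)
        assert p.phenotype_probs["CD86+"] == pytest.approx(0.085)

    def test_dermis_preset_population_parameters(self):
        p = fc.make_preset("dermis")
        assert p.rr_mean == pytest.approx(2.984)
        assert p.rr_cv == pytest.approx(108.05)
        assert p.layout == "clustered"
        assert p.phenotype_probs["CD206+"] == pytest.approx(0.359)
        assert p.phenotype_probs["CD86+"] == pytest.approx(0.206)

    def test_unknown_condition_lists_valid_names(self):
        with pytest.raises(ValueError, match="dermis.*tumor|tumor.*dermis"):
            fc.make_preset("liver")

    def test_yaml_round_trip(self, tmp_path):
        p = fc.make_preset("dermis", n_cells=12, seed=3)
        p.to_yaml(tmp_path / "p.yaml")
        q = fc.ScenePreset.from_yaml(tmp_path / "p.yaml")
        assert q == p

    @pytest.mark.parametrize(
        "bad", [dict(rr_mean=-1.0), dict(n_cells=-2), dict(layout="grid"),
                dict(phenotype_probs={"CD206+": 0.9, "CD86+": 0.5})]
    )
    def test_invalid_preset_rejected(self, bad):
        with pytest.raises(ValueError):
            fc.make_preset("tumor", **bad)


class TestPlacement:
    def test_zero_cells_empty_label_image(self):
        gt = fc.place_cells(fc.make_preset("tumor", n_cells=0, field_size=(64, 64)))
        assert gt.label_image.max() == 0
        assert gt.n_cells == 0

    def test_single_cell_disk_radius_in_range(self):
        p = fc.make_preset("tumor", n_cells=1, field_size=(64, 64), seed=5)
        gt = fc.place_cells(p)
        assert gt.label_image.max() == 1
        area = (gt.label_image == 1).sum()
        r_lo, r_hi = p.cell_radius_range
        # disk area bounds with rasterization slack
        assert np.pi * (r_lo - 1) ** 2 <= area <= np.pi * (r_hi + 1) ** 2

    def test_deterministic_given_seed(self):
        p = fc.make_preset("tumor", n_cells=50, field_size=(256, 256), seed=9)
        a = fc.place_cells(p)
        b = fc.place_cells(p)
        assert np.array_equal(a.label_image, b.label_image)
        assert a.per_cell.equals(b.per_cell)

    def test_every_labeled_pixel_has_one_owner(self):
        p = fc.make_preset("dermis", n_cells=30, field_size=(160, 160), seed=2)
        gt = fc.place_cells(p)
        labels = np.unique(gt.label_image)
        assert set(labels) == set(range(gt.n_cells + 1))
        # footprints never touch: no two distinct positive labels 8-adjacent
        lab = gt.label_image
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                shifted = np.roll(np.roll(lab, dy, 0), dx, 1)
                both = (lab > 0) & (shifted > 0)
                assert np.all(lab[both] == shifted[both])

    def test_clustered_layout_tighter_than_random(self):
        from scipy.spatial import cKDTree

        def mean_nn(gt):
            pts = gt.per_cell[["centroid_y", "centroid_x"]].to_numpy()
            d, _ = cKDTree(pts).query(pts, k=2)
            return d[:, 1].mean()

        clustered = fc.make_preset("dermis", n_cells=40, field_size=(192, 192), seed=11)
        random = clustered.replace(layout="random")
        assert mean_nn(fc.place_cells(clustered)) < mean_nn(fc.place_cells(random))

    def test_impossible_density_raises(self):
        p = fc.make_preset("tumor", n_cells=200, field_size=(32, 32), seed=0)
        with pytest.raises(RuntimeError, match="density|radius"):
            fc.place_cells(p)

    def test_phenotypes_are_valid_labels(self):
        gt = fc.place_cells(fc.make_preset("dermis", n_cells=40, field_size=(256, 256), seed=1))
        assert set(gt.per_cell["phenotype"]) <= set(PHENOTYPES)


class TestSynthesizeDecay:
    def test_zero_photons_zero_histogram(self, irf):
        h = fc.synthesize_decay(0.4, 2.5, 0.7, 0.0, irf, 0.0, rng=1)
        assert h.sum() == 0

    def test_mono_exponential_limit_with_delta_irf(self):
        """With a delta IRF and no offset the expected histogram is the
        wrapped exponential sampled at bin centers."""
        n_bins, period, tau = 128, 12.5, 1.7
        delta = IRF(histogram=np.eye(n_bins)[0], bin_width=period / n_bins)
        photons = 5e6
        h = fc.synthesize_decay(tau, 5.0, 1.0, 0.0, delta, photons,
                                period=period, n_bins=n_bins, rng=4)
        t = bin_centers(n_bins, period)
        expected = np.exp(-t / tau)
        expected *= photons / expected.sum()
        # Poisson relative error ~ 1/sqrt(counts); compare where counts are high
        big = expected > 1000
        assert np.allclose(h[big], expected[big], rtol=0.15)

    def test_first_moment_matches_brute_force_model(self, irf):
        """Empirical mean arrival time vs. the first moment of the expected
        histogram computed by an independent nested-loop circular
        convolution oracle."""
        tau1, tau2, alpha1, photons = 0.4, 2.5, 0.7, 1_000_000
        n_bins, period = irf.n_bins, 12.5
        t = bin_centers(n_bins, period)

        # oracle expected histogram: wrapped bi-exponential circularly
        # convolved with the IRF by explicit loops
        curve = alpha1 * np.exp(-t / tau1) / (1 - np.exp(-period / tau1)) + (
            1 - alpha1
        ) * np.exp(-t / tau2) / (1 - np.exp(-period / tau2))
        expected = np.zeros(n_bins)
        for k in range(n_bins):
            for j in range(n_bins):
                expected[k] += irf.histogram[j] * curve[(k - j) % n_bins]
        expected *= photons / expected.sum()
        model_mean = float((t * expected).sum() / expected.sum())
        model_var = float((t**2 * expected).sum() / expected.sum() - model_mean**2)

        h = fc.synthesize_decay(tau1, tau2, alpha1, 0.0, irf, photons, rng=12)
        empirical_mean = float((t * h).sum() / h.sum())
        se = np.sqrt(model_var / photons)
        assert abs(empirical_mean - model_mean) < 3 * se

    def test_invalid_parameters_rejected(self, irf):
        with pytest.raises(ValueError):
            fc.synthesize_decay(-0.4, 2.5, 0.7, 0.0, irf, 100.0)
        with pytest.raises(ValueError):
            fc.synthesize_decay(2.5, 0.4, 0.7, 0.0, irf, 100.0)
        with pytest.raises(ValueError):
            fc.synthesize_decay(0.4, 2.5, 0.7, 0.0, irf, -5.0)


class TestRenderScene:
    def test_zero_cell_scene_mcherry_dark(self):
        stack, gt, _ = fc.render_scene(
            fc.make_preset("tumor", n_cells=0, field_size=(48, 48), seed=3)
        )
        assert stack.intensity("mCherry").sum() == 0
        assert gt.n_cells == 0

    def test_photon_conservation(self, small_scene):
        _, stack, _, _ = small_scene
        for c in stack.channels:
            assert np.array_equal(
                stack.intensity(c), stack.data[stack.channel_index(c)].sum(axis=-1)
            )

    def test_bit_identical_given_seed(self):
        p = fc.make_preset("dermis", n_cells=8, field_size=(80, 80), seed=21)
        s1, _, _ = fc.render_scene(p)
        s2, _, _ = fc.render_scene(p)
        assert np.array_equal(s1.data, s2.data)

    def test_single_cell_intensity_ratio_near_true_rr(self):
        """The in-expectation construction: footprint NADH/FAD intensity
        ratio approaches the drawn RR at high photon budget."""
        p = fc.make_preset(
            "tumor", n_cells=1, field_size=(64, 64), seed=17,
            photons_per_pixel_cell=20000,
        )
        stack, gt, _ = fc.render_scene(p)
        sel = gt.label_image == 1
        ratio = stack.intensity("NADH")[sel].sum() / stack.intensity("FAD")[sel].sum()
        assert ratio == pytest.approx(gt.per_cell["true_rr"].iloc[0], rel=0.02)

    def test_drawn_rr_population_statistics(self):
        """For n >= 300 drawn cells the sample mean is within 2 SE of the
        preset mean and the sample CV within 15% of the preset CV."""
        p = fc.make_preset("tumor", n_cells=500, field_size=(1024, 1024), seed=29)
        gt = fc.place_cells(p)
        rr = gt.per_cell["true_rr"].to_numpy()
        se = rr.std(ddof=1) / np.sqrt(rr.size)
        assert abs(rr.mean() - p.rr_mean) < 2 * se
        cv = rr.std(ddof=1) / rr.mean() * 100
        assert abs(cv - p.rr_cv) / p.rr_cv < 0.15
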
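"""The section generator: determinism, exact construction, photon statistics."""

import numpy as np
import pytest

import redoxmap as rm


class TestConfigValidation:
    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="16"):
            rm.generate_section(rm.GeneratorConfig(shape=(8, 64)))

    def test_overfull_area_fractions_rejected(self):
        subs = [rm.SubpopSpec("a", True, True, 0.5, 0.5, 0.7),
                rm.SubpopSpec("b", False, True, 0.5, 0.5, 0.6)]
        with pytest.raises(ValueError, match="sum"):
            rm.GeneratorConfig(subpop_spec=subs)

    def test_nonpositive_budget_rejected(self):
        with pytest.raises(ValueError, match="photon_budget"):
            rm.GeneratorConfig(photon_budget=0.0)


class TestGenerateSection:
    def test_deterministic_for_fixed_seed(self, small_config, small_section):
        again = rm.generate_section(small_config)
        assert np.array_equal(again.nadh.pixels, small_section.nadh.pixels)
        assert np.array_equal(again.fad.pixels, small_section.fad.pixels)
        assert np.array_equal(again.truth.region_label, small_section.truth.region_label)

    def test_ground_truth_invariants(self, small_section):
        t = small_section.truth
        assert t.orr_field.min() >= 0 and t.orr_field.max() <= 1
        assert t.alpha2_field.min() >= 0 and t.alpha2_field.max() <= 1
        assert t.orr_field.shape == t.mask_true.shape == t.pimo_field.shape
        assert not np.allclose(t.landmarks[0], t.landmarks[1])

    def test_single_region_mean_orr_by_construction(self):
        """A lone implanted region carries exactly its configured mean ORR."""
        cfg = rm.GeneratorConfig(
            shape=(96, 96), correlation_length=20.0, seed=3, noise=False,
            texture_sigma=0.0,
            subpop_spec=[rm.SubpopSpec("ros", False, True, 0.7, 0.5, 0.05)],
        )
        sec = rm.generate_section(cfg)
        t = sec.truth
        region = t.region_label == 1
        assert region.any()
        assert np.allclose(t.orr_field[region], 0.7)
        assert t.hif_field[region].all() and not t.pimo_field[region].any()

    def test_exact_area_fractions(self, small_section):
        t = small_section.truth
        n = t.mask_true.sum()
        for i, sub in enumerate(small_section.config.subpop_spec, start=1):
            frac = (t.region_label == i).sum() / n
            assert frac == pytest.approx(sub.area_fraction, abs=1.0 / n)  # rounding only

    def test_noise_free_orr_reconstruction_exact(self):
        cfg = rm.GeneratorConfig(shape=(64, 64), correlation_length=15.0,
                                 seed=4, noise=False)
        sec = rm.generate_section(cfg)
        model = rm.fit_calibration(rm.generate_calibration_records(cfg))
        orr = rm.compute_orr(rm.normalize_image(sec.nadh, model),
                             rm.normalize_image(sec.fad, model))
        err = np.abs(orr.pixels - sec.truth.orr_field)[orr.mask]
        assert err.max() < 1e-9

    def test_noisy_orr_within_monte_carlo_error(self):
        """With 1e4 photons/px the per-region ORR mean sits within 3 SE of truth."""
        budget = 1e4
        cfg = rm.GeneratorConfig(shape=(128, 128), correlation_length=30.0,
                                 subpop_separation_um=20.0, orr_halo_um=20.0,
                                 seed=5, photon_budget=budget, texture_sigma=0.0)
        sec = rm.generate_section(cfg)
        model = rm.fit_calibration(rm.generate_calibration_records(cfg))
        orr = rm.compute_orr(rm.normalize_image(sec.nadh, model),
                             rm.normalize_image(sec.fad, model))
        t = sec.truth
        for i, sub in enumerate(cfg.subpop_spec, start=1):
            region = (t.region_label == i) & orr.mask
            n = region.sum()
            if n == 0:
                continue
            p = sub.mean_orr
            # Poisson error propagation: var(ORR) ~ p(1-p)/N_photons per pixel
            se = np.sqrt(p * (1 - p) / budget / n)
            assert abs(orr.pixels[region].mean() - p) <= 3 * se


class TestGenerateFlimCube:
    def test_photon_budget_conserved(self):
        cfg = rm.GeneratorConfig(shape=(32, 32), photon_budget=2000.0, seed=6)
        cube = rm.generate_flim_cube(np.full((32, 32), 0.5), (0.4, 2.5), cfg)
        mean_total = cube.total_photons.mean()
        se = np.sqrt(2000.0 / cube.total_photons.size)
        assert abs(mean_total - 2000.0) <= 3 * se

    def test_pure_species_reach_circle(self):
        """alpha2 = 0 and 1 give single-exponential decays on the universal circle."""
        cfg = rm.GeneratorConfig(shape=(16, 16), photon_budget=1e5, seed=8, noise=False)
        for a2, tau in ((0.0, 0.4), (1.0, 2.5)):
            cube = rm.generate_flim_cube(np.full((4, 4), a2), (0.4, 2.5), cfg, n_bins=320)
            f = rm.phasor_transform(cube)
            G, S = f.G[0, 0], f.S[0, 0]
            assert abs((G - 0.5) ** 2 + S**2 - 0.25) < 5e-3
            assert S / G == pytest.approx(f.omega * tau, rel=0.01)

    def test_mixture_lies_on_chord(self):
        """alpha2 = 0.5 at 1e5 photons: phasor on the chord between pure species."""
        cfg = rm.GeneratorConfig(shape=(32, 32), photon_budget=1e5, seed=9)
        cube = rm.generate_flim_cube(np.full((32, 32), 0.5), (0.4, 2.5), cfg)
        f = rm.phasor_transform(cube)
        cfg0 = rm.GeneratorConfig(shape=(4, 4), photon_budget=1e5, seed=9, noise=False)
        pure = [rm.phasor_transform(
            rm.generate_flim_cube(np.full((4, 4), a), (0.4, 2.5), cfg0))
            for a in (0.0, 1.0)]
        p1 = np.array([pure[0].G[0, 0], pure[0].S[0, 0]])
        p2 = np.array([pure[1].G[0, 0], pure[1].S[0, 0]])
        centre = np.array([np.nanmean(f.G), np.nanmean(f.S)])
        # perpendicular distance from the chord
        d = p2 - p1
        d /= np.hypot(*d)
        offset = centre - p1
        perp = abs(offset[0] * d[1] - offset[1] * d[0])
        assert perp < 5e-4  # Monte-Carlo tolerance at 1e5 photons x 1024 px
        along = np.dot(offset, d) / np.hypot(*(p2 - p1))
        assert along == pytest.approx(0.5, abs=0.01)

    def test_lifetime_beyond_period_rejected(self):
        cfg = rm.GeneratorConfig(shape=(16, 16), seed=0)
        with pytest.raises(ValueError, match="period"):
            rm.generate_flim_cube(np.zeros((4, 4)), (0.4, 13.0), cfg)

    def test_deterministic(self):
        cfg = rm.GeneratorConfig(shape=(16, 16), photon_budget=500.0, seed=11)
        c1 = rm.generate_flim_cube(np.full((16, 16), 0.3), (0.4, 2.5), cfg)
        c2 = rm.generate_flim_cube(np.full((16, 16), 0.3), (0.4, 2.5), cfg)
        assert np.array_equal(c1.counts, c2.counts)


class TestMisregister:
    def test_identity_transform_is_noop(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        ident = rm.SimilarityTransform(1.0, 0.0, (0.0, 0.0))
        moved, (pf, pm) = rm.misregister([img], ident, np.array([[4.0, 5.0], [20.0, 25.0]]))
        assert np.allclose(moved[0], img)
        assert np.allclose(pf, pm)

    def test_pure_translation_landmark_offsets(self):
        t = rm.SimilarityTransform(1.0, 0.0, (10.0, -5.0))
        lm = np.array([[15.0, 20.0], [40.0, 50.0]])
        _, (pf, pm) = rm.misregister([np.zeros((64, 64))], t, lm)
        assert np.allclose(pf - pm, [10.0, -5.0])

    def test_landmark_pairs_are_exact_correspondences(self):
        t = rm.SimilarityTransform(1.05, np.deg2rad(7), (3.5, -8.2), center=(32.0, 32.0))
        lm = np.array([[10.0, 12.0], [50.0, 40.0]])
        _, (pf, pm) = rm.misregister([np.zeros((64, 64))], t, lm)
        assert np.abs(t(pm) - pf).max() < 1e-9

    def test_estimate_recovers_from_misregistered_landmarks(self):
        t = rm.SimilarityTransform(1.05, np.deg2rad(7), (6.0, 2.0), center=(32.0, 32.0))
        lm = np.array([[10.0, 12.0], [50.0, 40.0]])
        _, (pf, pm) = rm.misregister([np.zeros((64, 64))], t, lm)
        est = rm.estimate_similarity(pf, pm, round_translation=False)
        assert est.scale == pytest.approx(1.05, rel=1e-9)
        assert est.rotation == pytest.approx(np.deg2rad(7), abs=1e-9)
        assert np.abs(est(pm) - pf).max() < 1e-9
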
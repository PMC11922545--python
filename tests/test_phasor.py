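"""Phasor transform, line fitting, universal-circle lifetimes, and fractions."""

import numpy as np
import pytest

import redoxmap as rm
from redoxmap.phasor import analytic_phasor

OMEGA = 2 * np.pi * 0.08  # rad/ns at 80 MHz


def single_pixel_cube(counts):
    return rm.DecayCube(np.asarray(counts, dtype=float)[None, None, :])


class TestDecayCube:
    def test_window_must_fit_period(self):
        with pytest.raises(ValueError, match="period"):
            rm.DecayCube(np.zeros((2, 2, 512)))  # 20 ns > 12.5 ns

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rm.DecayCube(-np.ones((2, 2, 16)))

    def test_full_period_320_bins_allowed(self):
        cube = rm.DecayCube(np.zeros((2, 2, 320)))
        assert cube.n_bins * cube.bin_width_ns == pytest.approx(cube.period_ns)


class TestPhasorTransform:
    def test_delta_decay_zero_lifetime_limit(self):
        counts = np.zeros(256)
        counts[0] = 1000
        f = rm.phasor_transform(single_pixel_cube(counts))
        assert f.G[0, 0] == pytest.approx(1.0, abs=0.01)  # half-bin discretization
        assert f.S[0, 0] == pytest.approx(0.0, abs=0.01)

    def test_uniform_counts_vanish_by_orthogonality(self):
        f = rm.phasor_transform(single_pixel_cube(np.full(320, 50.0)))
        assert abs(f.G[0, 0]) < 1e-12 and abs(f.S[0, 0]) < 1e-12

    @pytest.mark.parametrize("tau", [0.4, 1.0, 2.5, 4.0])
    def test_single_exponential_hits_analytic_point(self, tau):
        """Full-period sampling reproduces G=1/(1+(wt)^2), S=wt/(1+(wt)^2)."""
        cfg = rm.GeneratorConfig(shape=(16, 16), photon_budget=1e5, seed=0, noise=False)
        cube = rm.generate_flim_cube(np.zeros((4, 4)), (tau, 6.0), cfg, n_bins=320)
        f = rm.phasor_transform(cube)
        G, S = f.G[0, 0], f.S[0, 0]
        assert abs((G - 0.5) ** 2 + S**2 - 0.25) < 1e-3
        assert S / G == pytest.approx(OMEGA * tau, rel=0.01)
        Ga, Sa = analytic_phasor(tau, OMEGA)
        assert (G, S) == pytest.approx((Ga, Sa), abs=2e-3)

    def test_zero_photon_pixels_masked(self):
        counts = np.zeros((2, 2, 64))
        counts[0, 0, 3] = 7
        f = rm.phasor_transform(rm.DecayCube(counts))
        assert f.valid[0, 0] and not f.valid[1, 1]
        assert np.isnan(f.G[1, 1])

    def test_phasor_linearity_of_mixtures(self):
        """Phasor of a summed decay is the photon-weighted mean of the parts."""
        cfg = rm.GeneratorConfig(shape=(16, 16), photon_budget=1e6, seed=0, noise=False)
        c1 = rm.generate_flim_cube(np.zeros((2, 2)), (0.4, 2.5), cfg)
        c2 = rm.generate_flim_cube(np.ones((2, 2)), (0.4, 2.5), cfg)
        mix = rm.DecayCube(0.25 * c1.counts + 0.75 * c2.counts)
        f1, f2, fm = (rm.phasor_transform(c) for c in (c1, c2, mix))
        assert fm.G[0, 0] == pytest.approx(0.25 * f1.G[0, 0] + 0.75 * f2.G[0, 0], abs=1e-9)
        assert fm.S[0, 0] == pytest.approx(0.25 * f1.S[0, 0] + 0.75 * f2.S[0, 0], abs=1e-9)

    def test_exponential_mixtures_stay_inside_universal_circle(self, rng):
        """Convex mixtures of exponential decays lie inside the circle."""
        t = (np.arange(320) + 0.5) * 0.0390625  # full 12.5 ns period
        period = 12.5
        counts = np.zeros((8, 8, 320))
        for i in range(8):
            for j in range(8):
                taus = rng.uniform(0.1, 6.0, 3)
                wts = rng.dirichlet(np.ones(3))
                for tau, wgt in zip(taus, wts):
                    counts[i, j] += wgt * np.exp(-t / tau) / (1 - np.exp(-period / tau))
        f = rm.phasor_transform(rm.DecayCube(1e6 * counts))
        radius2 = (f.G - 0.5) ** 2 + f.S**2
        assert np.all(radius2 <= 0.25 + 5e-3)


class TestFilterPhasor:
    def test_constant_field_unchanged(self):
        counts = np.zeros((6, 6, 64))
        counts[..., 2] = 100.0
        f = rm.filter_phasor(rm.phasor_transform(rm.DecayCube(counts)))
        assert np.allclose(f.G[f.valid], f.G[0, 0])

    def test_single_outlier_replaced_by_median(self):
        counts = np.zeros((5, 5, 64))
        counts[..., 2] = 100.0
        counts[2, 2] = 0.0
        counts[2, 2, 40] = 100.0  # outlier pixel with a late decay
        raw = rm.phasor_transform(rm.DecayCube(counts))
        filt = rm.filter_phasor(raw)
        assert filt.G[2, 2] == pytest.approx(raw.G[0, 0])

    def test_dim_pixels_dropped_and_fit_errors(self):
        counts = np.full((4, 4, 64), 0.0)
        counts[..., 0] = 14.0  # photons uniformly 14 < threshold 15
        f = rm.filter_phasor(rm.phasor_transform(rm.DecayCube(counts)))
        assert not f.valid.any()
        with pytest.raises(ValueError, match="insufficient"):
            rm.fit_phasor_line(f)


class TestPhasorLine:
    def test_two_points_interpolated_exactly(self):
        line = rm.fit_phasor_line(np.array([0.2, 0.8]), np.array([0.4, 0.1]))
        assert line.slope == pytest.approx(-0.5)
        assert line.intercept == pytest.approx(0.5)
        assert line.r_squared == 1.0

    def test_noiseless_chord_recovered(self, rng):
        g = rng.uniform(0.3, 0.9, 50)
        s = -0.4 * g + 0.55
        line = rm.fit_phasor_line(g, s)
        assert line.slope == pytest.approx(-0.4, abs=1e-12)
        assert line.intercept == pytest.approx(0.55, abs=1e-12)

    def test_vertical_line_rejected(self):
        with pytest.raises(ValueError, match="vertical"):
            rm.fit_phasor_line(np.array([0.5, 0.5, 0.5]), np.array([0.1, 0.2, 0.3]))

    def test_mixture_line_passes_through_pure_species_points(self):
        cfg = rm.GeneratorConfig(shape=(8, 8), photon_budget=1e6, seed=0, noise=False)
        a2 = np.tile(np.linspace(0.1, 0.9, 8), (8, 1))
        cube = rm.generate_flim_cube(a2, (0.4, 2.5), cfg)
        f = rm.phasor_transform(cube)
        line = rm.fit_phasor_line(f)
        for tau in (0.4, 2.5):
            cube_p = rm.generate_flim_cube(np.zeros((2, 2)) if tau == 0.4 else np.ones((2, 2)),
                                           (0.4, 2.5), cfg)
            fp = rm.phasor_transform(cube_p)
            G, S = fp.G[0, 0], fp.S[0, 0]
            assert abs(line.slope * G + line.intercept - S) < 1e-3


class TestCircleIntersections:
    def test_chord_through_two_known_species(self):
        """Line through the exact phasor points of 0.4 and 2.5 ns."""
        p1 = analytic_phasor(0.4, OMEGA)
        p2 = analytic_phasor(2.5, OMEGA)
        slope = (p2[1] - p1[1]) / (p2[0] - p1[0])
        line = rm.PhasorLine(slope, p1[1] - slope * p1[0], 1.0, 2)
        inter = rm.circle_intersections(line, OMEGA)
        assert inter.tau1 == pytest.approx(0.4, abs=1e-6)
        assert inter.tau2 == pytest.approx(2.5, abs=1e-6)

    def test_line_through_origin_point_gives_zero_lifetime(self):
        """A line through (1, 0) and the 2.5 ns point yields tau = 0 and 2.5."""
        p2 = analytic_phasor(2.5, OMEGA)
        slope = (p2[1] - 0.0) / (p2[0] - 1.0)
        line = rm.PhasorLine(slope, -slope, 1.0, 2)  # passes through (1, 0)
        inter = rm.circle_intersections(line, OMEGA)
        assert inter.tau1 == pytest.approx(0.0, abs=1e-9)
        assert inter.tau2 == pytest.approx(2.5, abs=1e-6)

    def test_horizontal_tangent_rejected(self):
        line = rm.PhasorLine(0.0, 0.0, 1.0, 2)  # S = 0: meets circle at G=0 and G=1
        with pytest.raises(ValueError, match="two-species"):
            rm.circle_intersections(line, OMEGA)

    def test_missing_line_rejected(self):
        line = rm.PhasorLine(0.0, 0.9, 1.0, 2)
        with pytest.raises(ValueError, match="two-species"):
            rm.circle_intersections(line, OMEGA)


class TestProjectFractions:
    def _geometry(self):
        p1 = analytic_phasor(0.4, OMEGA)
        p2 = analytic_phasor(2.5, OMEGA)
        slope = (p2[1] - p1[1]) / (p2[0] - p1[0])
        line = rm.PhasorLine(slope, p1[1] - slope * p1[0], 1.0, 2)
        return line, rm.circle_intersections(line, OMEGA)

    def _field(self, G, S):
        G = np.asarray(G, dtype=float)
        return rm.PhasorField(G=G, S=np.asarray(S, dtype=float),
                              photons=np.full(G.shape, 100.0), harmonic=1,
                              omega=OMEGA, valid=np.ones(G.shape, bool))

    def test_pixel_at_free_point(self):
        line, inter = self._geometry()
        f = self._field([[inter.free_point[0]]], [[inter.free_point[1]]])
        comp = rm.project_fractions(f, line, inter)
        assert comp.alpha2[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert comp.tau_m[0, 0] == pytest.approx(inter.tau1)

    def test_pixel_at_chord_midpoint(self):
        line, inter = self._geometry()
        mid = (np.array(inter.free_point) + np.array(inter.bound_point)) / 2
        comp = rm.project_fractions(self._field([[mid[0]]], [[mid[1]]]), line, inter)
        assert comp.alpha2[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert comp.tau_m[0, 0] == pytest.approx((inter.tau1 + inter.tau2) / 2)

    def test_fractions_sum_to_one_and_tau_m_bounded(self, rng):
        line, inter = self._geometry()
        G = rng.uniform(0.2, 1.0, (16, 16))
        S = rng.uniform(0.0, 0.6, (16, 16))
        comp = rm.project_fractions(self._field(G, S), line, inter)
        assert np.all(comp.alpha1 + comp.alpha2 == 1.0)
        assert np.all(comp.tau_m >= inter.tau1) and np.all(comp.tau_m <= inter.tau2)
        assert np.all((comp.alpha2 >= 0) & (comp.alpha2 <= 1))
        assert np.allclose(comp.bound_percent, 100 * comp.alpha2)

    def test_recovers_known_bound_fraction_levels(self):
        """Synthetic cube with alpha2 in {0.2, 0.5, 0.8}: per-level means within 0.03."""
        a2 = np.zeros((48, 48))
        a2[:16], a2[16:32], a2[32:] = 0.2, 0.5, 0.8
        cfg = rm.GeneratorConfig(shape=(48, 48), photon_budget=1e4, seed=7)
        cube = rm.generate_flim_cube(a2, (0.4, 2.5), cfg)
        field = rm.filter_phasor(rm.phasor_transform(cube))
        line = rm.fit_phasor_line(field)
        inter = rm.circle_intersections(line, field.omega)
        comp = rm.project_fractions(field, line, inter)
        # interior rows only: the 3x3 median mixes rows at band boundaries
        for level, rows in ((0.2, slice(1, 15)), (0.5, slice(17, 31)), (0.8, slice(33, 47))):
            assert np.nanmean(comp.alpha2[rows]) == pytest.approx(level, abs=0.03)


def test_two_species_report_flags_off_line_cloud(rng):
    g = rng.uniform(0.3, 0.9, 200)
    s = -0.4 * g + 0.55
    field = rm.PhasorField(G=g.reshape(10, 20), S=s.reshape(10, 20),
                           photons=np.full((10, 20), 100.0), harmonic=1,
                           omega=OMEGA, valid=np.ones((10, 20), bool))
    line = rm.fit_phasor_line(field)
    report = rm.two_species_report(field, line)
    assert report["fraction_far_from_line"] == 0.0
    noisy = rm.PhasorField(G=field.G, S=field.S + rng.choice([0.0, 0.2], (10, 20)),
                           photons=field.photons, harmonic=1, omega=OMEGA,
                           valid=field.valid)
    report2 = rm.two_species_report(noisy, line)
    assert report2["fraction_far_from_line"] > 0.2
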
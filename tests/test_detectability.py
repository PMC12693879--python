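"""Task function, NPW detectability, d' comparisons and HU linearity."""

from __future__ import annotations

import math

import numpy as np
import pytest

import ctiq
from ctiq.detectability import (
    compare_dprime,
    detectability_index,
    disc_transform,
    hu_linearity,
    task_function,
)
from ctiq.nps import NpsResult, nps_2d, NoiseRoiSet
from ctiq.phantom import NoiseKernel
from ctiq.published import DPRIME_TABLE
from ctiq.resolution import TtfResult

from conftest import make_flat_stack


def freq_grid(n=256, fmax=4.0):
    return np.linspace(-fmax, fmax, n, endpoint=False)


def white_nps(n=256, fmax=4.0, level=25.0):
    f = freq_grid(n, fmax)
    return NpsResult(nps2d=np.full((n, n), level), fx=f, fy=f)


class TestTaskFunction:
    def test_dc_value_is_contrast_times_area(self):
        f = freq_grid()
        task = task_function(5.0, 10.0, f, f)
        i0 = np.argmin(np.abs(f))
        assert task.w[i0, i0] == pytest.approx(10.0 * math.pi * 2.5**2)
        assert task.w[i0, i0] == pytest.approx(196.35, abs=0.01)

    def test_radial_symmetry(self):
        f = freq_grid(128)
        task = task_function(5.0, 10.0, f, f)
        assert np.allclose(task.w, task.w.T)
        assert np.allclose(task.w[1:, 1:], task.w[1:, 1:][::-1, ::-1])

    def test_parseval_for_disc(self):
        # II |W|^2 du dv = C^2 * pi r^2 (energy of the spatial disc)
        f = freq_grid(512, 8.0)
        task = task_function(5.0, 10.0, f, f)
        df = f[1] - f[0]
        integral = (task.w**2).sum() * df * df
        assert integral == pytest.approx(100.0 * math.pi * 2.5**2, rel=0.01)
        assert integral == pytest.approx(1963.5, rel=0.01)

    def test_matches_rasterized_disc_dft_oracle(self):
        # oracle: DFT of a finely rasterised (supersampled) disc
        n, d, ss = 512, 0.1, 4
        coords = (np.arange(n * ss) - (n * ss - 1) / 2) * (d / ss)
        X, Y = np.meshgrid(coords, coords)
        disc = (np.hypot(X, Y) <= 2.5).astype(float) * 10.0
        disc = disc.reshape(n, ss, n, ss).mean(axis=(1, 3))
        w_dft = np.abs(np.fft.fftshift(np.fft.fft2(disc))) * d * d
        f = np.fft.fftshift(np.fft.fftfreq(n, d))
        analytic = np.abs(disc_transform(np.hypot(*np.meshgrid(f, f)), 5.0, 10.0))
        # compare well below the transform's first zero (rho ~ 0.244 for a
        # 5 mm disc), where the relative scale is meaningful
        low = np.hypot(*np.meshgrid(f, f)) < 0.2
        np.testing.assert_allclose(w_dft[low], analytic[low], rtol=0.01)

    def test_truncated_grid_warns(self):
        f = np.linspace(-0.1, 0.1, 16, endpoint=False)
        with pytest.warns(UserWarning, match="truncated"):
            task_function(5.0, 10.0, f, f)

    def test_bad_diameter(self):
        f = freq_grid(32)
        with pytest.raises(ValueError):
            task_function(0.0, 10.0, f, f)


class TestDetectabilityIndex:
    def closed_form(self, C, r, N0):
        return C * math.sqrt(math.pi * r * r / N0)

    @pytest.mark.parametrize("C,N0", [(10.0, 25.0), (30.0, 4.0), (120.0, 100.0)])
    def test_closed_form_white_nps_flat_ttf(self, C, N0):
        f = freq_grid(256, 4.0)
        nps = white_nps(256, 4.0, N0)
        task = task_function(5.0, C, f, f)
        res = detectability_index(None, nps, task)
        assert res.dprime == pytest.approx(self.closed_form(C, 2.5, N0), rel=0.01)

    def test_reference_scalar(self):
        # C=10 HU, r=2.5 mm, N0=25 HU^2 mm^2 -> d' = 8.862
        assert self.closed_form(10.0, 2.5, 25.0) == pytest.approx(8.862, abs=5e-4)

    def test_zero_contrast_zero_dprime(self):
        f = freq_grid(128)
        res = detectability_index(None, white_nps(128), task_function(5.0, 0.0, f, f))
        assert res.dprime == 0.0

    def test_doubling_contrast_doubles_dprime(self):
        f = freq_grid(128)
        nps = white_nps(128)
        a = detectability_index(None, nps, task_function(5.0, 10.0, f, f))
        b = detectability_index(None, nps, task_function(5.0, 20.0, f, f))
        assert b.dprime == pytest.approx(2 * a.dprime, rel=1e-9)

    def test_nps_scaling_law_exact(self):
        # scaling NPS by k scales d' by 1/sqrt(k)
        f = freq_grid(128)
        task = task_function(5.0, 10.0, f, f)
        a = detectability_index(None, white_nps(128, level=25.0), task)
        for k in (0.25, 4.0, 9.0):
            b = detectability_index(None, white_nps(128, level=25.0 * k), task)
            assert b.dprime == pytest.approx(a.dprime / math.sqrt(k), rel=1e-9)

    def test_zero_noise_flags_infinite(self):
        f = freq_grid(64)
        res = detectability_index(None, white_nps(64, level=0.0),
                                  task_function(5.0, 10.0, f, f))
        assert res.infinite and math.isinf(res.dprime)

    def test_grid_mismatch_rejected(self):
        f = freq_grid(64)
        task = task_function(5.0, 10.0, f, f)
        with pytest.raises(ValueError, match="grid"):
            detectability_index(None, white_nps(128), task)

    def test_ttf_attenuates_dprime(self):
        f = freq_grid(128)
        nps = white_nps(128)
        task = task_function(5.0, 10.0, f, f)
        ideal = detectability_index(None, nps, task)
        ttf = TtfResult(frequency=np.linspace(0, 6, 200),
                        ttf=np.exp(-np.linspace(0, 6, 200)))
        blurred = detectability_index(ttf, nps, task)
        assert 0 < blurred.dprime < ideal.dprime
        assert not blurred.ttf_truncated

    def test_end_to_end_recovery_within_5pct(self, single_insert_geometry, fine_grid):
        # pipeline d' (measured TTF + measured NPS) vs the analytic value
        # from the true blur MTF and the true white NPS
        sigma_b, sigma_n, d_px = 0.3, 10.0, 0.2

        truth = ctiq.GroundTruth(background_hu=20.0, blur_sigma_mm=sigma_b,
                                 noise_sigma_hu=4.0, seed=12)
        stack, _ = ctiq.render_module(single_insert_geometry, "sensitometry",
                                      truth, fine_grid, n_slices=5)
        esf = ctiq.esf_from_insert(stack, single_insert_geometry.inserts[0],
                                   single_insert_geometry.center_of("sensitometry"))
        ttf = ctiq.ttf_from_esf(esf)

        # large ROIs: the detrend-suppressed lowest-frequency cells must be
        # a negligible fraction of the disc task's passband
        noise = ctiq.add_correlated_noise(
            make_flat_stack(0.0, shape=(48, 256, 256), spacing=(d_px, d_px)),
            sigma_n, NoiseKernel.white(), seed=13)
        rois = NoiseRoiSet(blocks=list(noise.voxels), pixel_spacing=(d_px, d_px))
        nps = nps_2d(rois)

        task = task_function(5.0, 30.0, nps.fx, nps.fy)
        measured = detectability_index(ttf, nps, task).dprime

        # independent analytic path: direct Riemann sums with the truth
        U, V = np.meshgrid(nps.fx, nps.fy)
        rho = np.hypot(U, V)
        W = disc_transform(rho, 5.0, 30.0)
        T = np.exp(-2 * math.pi**2 * sigma_b**2 * rho**2)
        N0 = sigma_n**2 * d_px * d_px
        du = nps.fx[1] - nps.fx[0]
        num = (W**2 * T**2).sum() * du * du
        den = (W**2 * T**2 * N0).sum() * du * du
        analytic = math.sqrt(num * num / den)
        assert measured == pytest.approx(analytic, rel=0.05)


class TestCompareDprime:
    def test_equal_values(self):
        res = compare_dprime("a", 5.0, "b", 5.0)
        assert res.difference == 0.0
        assert res.percent == 0.0

    def test_worked_example_thorax_abdomen(self):
        res = compare_dprime("standard", 10.62, "uhr", 6.66)
        assert res.difference == pytest.approx(3.96, abs=1e-9)
        assert res.percent == pytest.approx(37.29, abs=0.01)

    def test_worked_example_inner_ear(self):
        res = compare_dprime("0.4 mm", 10.59, "0.2 mm", 6.13)
        assert res.percent == pytest.approx(42.1, abs=0.05)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            _ = compare_dprime("a", 0.0, "b", 1.0).percent

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            compare_dprime("a", math.inf, "b", 1.0)

    def test_published_table_comparisons(self):
        # every protocol-comparison figure recomputed from the published d'
        t = DPRIME_TABLE
        ie = compare_dprime("0.4mm", t["Hr72 (13.3 mGy), 0.4 mm"]["acrylic"],
                            "uhr", t["UHR Hr72 (13.5 mGy)"]["acrylic"])
        assert round(ie.percent) == 42
        ie_low = compare_dprime("0.4mm", t["Hr72 (5.04 mGy), 0.4 mm"]["acrylic"],
                                "uhr", t["UHR Hr72 (5.12 mGy)"]["acrylic"])
        assert ie_low.percent == pytest.approx(100 * (3.93 - 3.38) / 3.93, rel=1e-12)
        ta = compare_dprime("0.4mm", t["Br40 (11.6 mGy), 0.4 mm"]["acrylic"],
                            "uhr", t["UHR Br40 (11.6 mGy)"]["acrylic"])
        assert ta.percent == pytest.approx(37.3, abs=0.05)
        assert ta.difference == pytest.approx(3.96, abs=1e-9)
        air = compare_dprime("0.4mm", t["Br40 (11.6 mGy), 0.4 mm"]["air"],
                             "uhr", t["UHR Br40 (11.6 mGy)"]["air"])
        assert air.difference == pytest.approx(138.82, abs=1e-9)


class TestHuLinearity:
    def test_collinear_r2_is_one(self):
        res = hu_linearity([(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)])
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_perturbed_point_matches_normal_equations_oracle(self):
        pairs = [(-1000.0, 0.0), (-35.0, 0.19), (120.0, 0.215),
                 (340.0, 0.26), (995.0, 0.33)]  # last point off the line
        res = hu_linearity(pairs)
        hu = np.array([p[0] for p in pairs])
        mu = np.array([p[1] for p in pairs])
        A = np.column_stack([mu, np.ones_like(mu)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ hu)
        pred = slope * mu + intercept
        r2 = 1 - ((hu - pred) ** 2).sum() / ((hu - hu.mean()) ** 2).sum()
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-12)
        assert res.r_squared == pytest.approx(r2, rel=1e-12)
        assert res.r_squared < 1.0

    def test_r2_bounds(self):
        rng = np.random.default_rng(21)
        mu = np.linspace(0.1, 0.5, 7)
        hu = 5000 * mu - 1000 + rng.normal(0, 50, 7)
        res = hu_linearity(list(zip(hu, mu)))
        assert 0.0 <= res.r_squared <= 1.0

    def test_degenerate_mu_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hu_linearity([(0.0, 1.0), (1.0, 1.0), (2.0, 1.0)])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            hu_linearity([(0.0, 1.0), (1.0, 2.0)])

    def test_simulated_insert_pipeline_linearity(self, geometry, grid):
        # measured insert HUs against a mu table consistent with them
        truth = ctiq.GroundTruth(background_hu=20.0, noise_sigma_hu=3.0, seed=30)
        stack, _ = ctiq.render_module(geometry, "sensitometry", truth, grid)
        mu_water = 0.2
        pairs = []
        for ins in geometry.inserts:
            stats = ctiq.insert_hu(stack, ins, geometry.center_of("sensitometry"))
            mu = mu_water * (1 + ins.nominal_hu / 1000.0)  # HU definition inverted
            pairs.append((stats.mean, mu))
        res = hu_linearity(pairs)
        assert res.r_squared > 0.999
        assert res.slope == pytest.approx(1000.0 / mu_water, rel=0.02)
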
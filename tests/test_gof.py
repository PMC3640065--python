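"""Pixel/slice chi-squared statistics and slice ranking."""

import numpy as np
import pytest

from dtiqa import dti_core, gof
from dtiqa.io_formats import DwiStudy
from dtiqa.phantom import PhantomSpec, SliceArtifact, generate

from conftest import SMALL_GRID


class TestChiPixel:
    def test_perfect_fit_is_zero(self):
        s = np.full(6, 0.5)
        assert gof.chi_pixel(s, s) == 0.0

    def test_hand_arithmetic(self):
        # (0.01/0.25) + (0.01/0.25) = 0.08
        val = gof.chi_pixel(np.array([0.5, 0.5]), np.array([0.4, 0.6]))
        assert val == pytest.approx(0.08, rel=1e-12)

    def test_quadratic_in_residuals(self):
        s_m = np.array([0.5, 0.5])
        v1 = gof.chi_pixel(s_m, np.array([0.45, 0.55]))
        v2 = gof.chi_pixel(s_m, np.array([0.40, 0.60]))
        assert v2 == pytest.approx(4 * v1, rel=1e-12)

    def test_all_zero_measured_is_missing(self):
        val = gof.chi_pixel(np.zeros(4), np.full(4, 0.1))
        assert np.isnan(val)


class TestChiSlice:
    def test_hand_arithmetic_with_j_over_k(self):
        """K = 2 voxels, J = 4: (J/K) * sum of per-voxel terms = 2 * 0.08."""
        # minimal stand-in fit object: chi_slice only needs signals/mask/J
        from types import SimpleNamespace

        scheme = SimpleNamespace(J=4)
        mask = np.zeros((1, 2, 1), dtype=bool)
        mask[0, :, 0] = True
        s_m = np.array(
            [[0.5, 0.5, 0.5, 0.5],
             [0.5, 0.5, 0.5, 0.5]]
        )
        # per-voxel normalized squared errors 0.02 and 0.06 on DWI 0
        e1 = np.sqrt(0.02) * 0.5
        e2 = np.sqrt(0.06) * 0.5
        s_f = s_m.copy()
        s_f[0, 0] += e1
        s_f[1, 0] -= e2
        fit = dti_core.TensorFit(
            tensors=None, eigenvalues=None, e1=None, fa=None, md=None,
            squared_error=None, mask=mask, s_measured=s_m, s_fitted=s_f,
            scheme=scheme,
        )
        mat = gof.chi_slice_matrix(fit)
        assert mat.shape == (1, 4)
        assert mat[0, 0] == pytest.approx((4 / 2) * 0.08, rel=1e-12)
        assert mat[0, 1] == 0.0

    def test_zero_for_perfect_fit_and_nan_outside_brain(self, clean_phantom):
        study, _ = clean_phantom
        fit = dti_core.fit_study(study)
        mat = gof.chi_slice_matrix(fit)
        has_brain = np.isfinite(mat).any(axis=1)
        assert np.nanmax(mat) == pytest.approx(0.0, abs=1e-18)
        # ellipsoid does not reach the first/last axial slice rows? it does
        # at 0.46*nz semi-axis, so at least assert NaN rows are all-NaN
        assert np.all(np.isnan(mat[~has_brain]))

    def test_intensity_scale_invariance(self, noisy_phantom):
        """Scaling b0 and DWIs jointly leaves both statistics unchanged."""
        study, _ = noisy_phantom
        fit1 = dti_core.fit_study(study)
        scaled = DwiStudy(
            b0=study.b0 * 7.5, dwis=study.dwis * 7.5, mask=study.mask,
            scheme=study.scheme, labels=study.labels,
        )
        fit2 = dti_core.fit_study(scaled)
        m1 = gof.compute_gof(fit1)
        m2 = gof.compute_gof(fit2)
        np.testing.assert_allclose(m1.chi_slice, m2.chi_slice, rtol=1e-9)
        np.testing.assert_allclose(
            m1.chi_pix[fit1.mask], m2.chi_pix[fit2.mask], rtol=1e-9
        )


@pytest.fixture(scope="module")
def injected():
    spec = PhantomSpec(
        grid_shape=SMALL_GRID, noise_sigma=20.0, seed=6,
        artifacts=[SliceArtifact(z=10, j=3, offset=400.0)],
    )
    study, _ = generate(spec)
    fit = dti_core.fit_study(study)
    return gof.chi_slice_matrix(fit)


class TestInjectionDetection:
    def test_injected_slice_is_matrix_maximum(self, injected):
        mat = injected
        z, j = np.unravel_index(np.nanargmax(mat), mat.shape)
        assert (z, j) == (10, 3)

    def test_corrupted_gradient_stripes_vertically(self):
        """A whole corrupted DWI elevates its column across most slices."""
        spec = PhantomSpec(grid_shape=SMALL_GRID, noise_sigma=40.0, seed=6,
                           artifacts=[])
        study, _ = generate(spec)
        dwis = study.dwis.copy()
        dwis[..., 7] *= 0.5  # attenuate one gradient volume everywhere
        corrupted = DwiStudy(b0=study.b0, dwis=dwis, mask=study.mask,
                             scheme=study.scheme, labels=study.labels)
        mat = gof.chi_slice_matrix(dti_core.fit_study(corrupted))
        col_means = np.nanmean(mat, axis=0)
        others = np.delete(col_means, 7)
        assert col_means[7] > np.percentile(others, 95)


class TestHistogram:
    def test_noiseless_single_mode_near_zero(self, clean_phantom):
        study, _ = clean_phantom
        fit = dti_core.fit_study(study)
        maps = gof.compute_gof(fit)
        h = gof.chi_histogram(maps.chi_pix)
        assert h.signal_mode == pytest.approx(0.0, abs=1e-12)

    def test_air_in_mask_makes_noise_lobe(self, noisy_phantom):
        """Including background voxels produces a high-valued noise lobe."""
        study, _ = noisy_phantom
        wide_mask = np.ones(study.grid_shape, dtype=bool)
        wide = DwiStudy(b0=np.maximum(study.b0, 1e-3), dwis=study.dwis,
                        mask=wide_mask, scheme=study.scheme)
        fit = dti_core.fit_study(wide)
        maps = gof.compute_gof(fit)
        h = gof.chi_histogram(maps.chi_pix)
        assert h.noise_mode > h.signal_mode

    def test_zoom_window_monotone_in_percentile(self, noisy_fit):
        maps = gof.compute_gof(noisy_fit)
        lows = [
            gof.chi_histogram(maps.chi_pix, zoom_percentile=p).zoom_window[0]
            for p in (80, 90, 95, 99)
        ]
        assert np.all(np.diff(lows) > 0)

    def test_too_few_voxels_raises(self):
        with pytest.raises(ValueError, match="100"):
            gof.chi_histogram(np.ones(10))


class TestBestWorstSlices:
    def test_tie_break_by_index_order(self):
        mat = np.ones((10, 4))
        bands = gof.best_worst_slices(mat, n_bands=5, n_each=5)
        assert len(bands) == 5
        first = bands[0]
        assert first["best"] == first["worst"]
        assert first["best"][0] == (0, 0)
        assert first["best"][1] == (0, 1)

    def test_short_band_flagged(self):
        mat = np.full((5, 2), np.nan)
        mat[0, 0] = 1.0
        mat[2, 0] = 2.0
        mat[4, 1] = 3.0
        bands = gof.best_worst_slices(mat, n_bands=5, n_each=5)
        assert all(b["short"] for b in bands)

    def test_injected_artifact_in_exactly_one_worst_list(self):
        rng = np.random.default_rng(2)
        mat = rng.uniform(0.0, 0.01, size=(20, 8))
        mat[10, 3] = 5.0
        bands = gof.best_worst_slices(mat)
        hits = [b["band"] for b in bands if (10, 3) in b["worst"]]
        assert len(hits) == 1
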
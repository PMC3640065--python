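"""Tensor model, log-linear fitting and scalar maps."""

import numpy as np
import pytest

from dtiqa import dti_core
from dtiqa.io_formats import DwiStudy, GradientScheme
from dtiqa.phantom import tensor_from_fa_md

from conftest import random_spd_tensors


class TestForwardSignal:
    def test_zero_tensor_gives_unit_signal(self, scheme32):
        s = dti_core.forward_signal(np.zeros(6), scheme32)
        np.testing.assert_allclose(s, 1.0)

    def test_isotropic_tensor_attenuates_uniformly(self, scheme32):
        d = 1e-3
        s = dti_core.forward_signal(np.r_[d, d, d, 0, 0, 0], scheme32)
        np.testing.assert_allclose(s, np.exp(-scheme32.b_value * d), rtol=1e-12)

    def test_hand_evaluated_attenuation(self, directions32):
        # D = diag(1.7, 0.2, 0.2)e-3, b = 700, g = x: S = exp(-700 * 1.7e-3)
        dirs = np.vstack([np.eye(3), directions32[:4]])
        scheme = GradientScheme(700.0, dirs)
        d6 = np.r_[1.7e-3, 0.2e-3, 0.2e-3, 0, 0, 0]
        s = dti_core.forward_signal(d6, scheme)
        assert s[0] == pytest.approx(np.exp(-1.19), rel=1e-12)


class TestFitTensorLLS:
    def test_noiseless_round_trip_many_tensors(self, scheme32):
        """Noise-free forward signals invert to the generating tensor."""
        rng = np.random.default_rng(7)
        d6 = random_spd_tensors(100, rng)
        s = dti_core.forward_signal(d6, scheme32)
        d_hat = dti_core.fit_tensor_lls(s, scheme32)
        np.testing.assert_allclose(d_hat, d6, rtol=1e-10, atol=1e-16)

    def test_unit_signals_give_zero_tensor(self, scheme32):
        d = dti_core.fit_tensor_lls(np.ones(scheme32.J), scheme32)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        fa, md = dti_core.fa_md_from_tensors(d)
        assert fa == 0.0 and md == pytest.approx(0.0, abs=1e-15)

    def test_prolate_tensor_fa_value(self, scheme32):
        """FA of eigenvalues (1.7, 0.2, 0.2)e-3 equals sqrt(1.5*1.5/2.97)."""
        d6 = np.r_[1.7e-3, 0.2e-3, 0.2e-3, 0, 0, 0]
        s = dti_core.forward_signal(d6, scheme32)
        fa, md = dti_core.fa_md_from_tensors(dti_core.fit_tensor_lls(s, scheme32))
        assert fa == pytest.approx(0.8703882797784892, abs=1e-8)
        assert md == pytest.approx(0.7e-3, rel=1e-10)

    def test_degenerate_gradient_table_raises(self):
        g = np.tile([1.0, 0.0, 0.0], (8, 1))
        scheme = GradientScheme(700.0, g)
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            dti_core.fit_tensor_lls(np.full(8, 0.5), scheme)

    def test_clamping_handles_nonpositive_signals(self, scheme32):
        s = dti_core.forward_signal(np.r_[1e-3, 1e-3, 1e-3, 0, 0, 0], scheme32)
        s_bad = s.copy()
        s_bad[3] = 0.0
        s_bad[5] = -0.2
        d = dti_core.fit_tensor_lls(s_bad, scheme32)
        assert np.all(np.isfinite(d))


class TestEigenAndMaps:
    def test_closed_form_eigenvalues_match_lapack(self):
        rng = np.random.default_rng(0)
        d6 = random_spd_tensors(200, rng) + 1e-4 * rng.standard_normal((200, 6))
        ours = dti_core.eigvals_sym3(d6)
        ref = np.linalg.eigvalsh(dti_core.tensor_to_matrix(d6))[:, ::-1]
        np.testing.assert_allclose(ours, ref, rtol=1e-8, atol=1e-12)

    def test_fa_limits(self):
        assert dti_core.fa_from_eigvals([1e-3, 1e-3, 1e-3]) == 0.0
        assert dti_core.fa_from_eigvals([1e-3, 0.0, 0.0]) == pytest.approx(1.0)
        assert dti_core.fa_from_eigvals([0.0, 0.0, 0.0]) == 0.0

    def test_md_is_eigenvalue_mean(self):
        lam = np.array([1.7e-3, 0.2e-3, 0.2e-3])
        assert lam.mean() == pytest.approx(0.7e-3)
        fa, md = dti_core.fa_md_from_tensors(np.r_[lam, 0, 0, 0])
        assert md == pytest.approx(0.7e-3)

    def test_fa_rotation_invariance(self):
        """FA(R D R') = FA(D) for random rotations."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        d6 = random_spd_tensors(50, rng)
        mats = dti_core.tensor_to_matrix(d6)
        R = Rotation.random(50, rng=rng).as_matrix()
        rotated = dti_core.matrix_to_tensor(R @ mats @ R.transpose(0, 2, 1))
        fa0, _ = dti_core.fa_md_from_tensors(d6)
        fa1, _ = dti_core.fa_md_from_tensors(rotated)
        np.testing.assert_allclose(fa0, fa1, atol=1e-10)

    def test_fa_monotone_in_anisotropy_at_fixed_md(self):
        md = 0.7e-3
        ratios = np.linspace(1.0, 50.0, 25)
        fas = []
        for r in ratios:
            lam3 = 3 * md / (r + 2)
            lam1 = r * lam3
            fas.append(dti_core.fa_from_eigvals([lam1, lam3, lam3]))
        assert np.all(np.diff(fas) > 0)

    def test_scalar_maps_shapes_and_e1_norm(self, noisy_fit):
        fit = noisy_fit
        inm = fit.mask
        assert fit.fa[inm].min() >= 0 and fit.fa[inm].max() <= 1
        norms = np.linalg.norm(fit.e1[inm], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)
        lam = fit.eigenvalues[inm]
        assert np.all(np.diff(lam, axis=1) <= 1e-18)  # descending


class TestNormalize:
    def _study(self, scheme32, b0_val=100.0):
        shape = (4, 4, 3)
        b0 = np.full(shape, b0_val)
        dwis = np.full(shape + (scheme32.J,), b0_val)
        mask = np.ones(shape, bool)
        return DwiStudy(b0=b0, dwis=dwis, mask=mask, scheme=scheme32)

    def test_identity_when_dwi_equals_b0(self, scheme32):
        s_m, m = dti_core.normalize(self._study(scheme32))
        np.testing.assert_allclose(s_m, 1.0)
        assert m.sum() == 48

    def test_zero_b0_voxel_dropped(self, scheme32):
        study = self._study(scheme32)
        study.b0[0, 0, 0] = 0.0
        s_m, m = dti_core.normalize(study)
        assert not m[0, 0, 0]
        assert s_m.shape[0] == 47

    def test_empty_mask_raises(self, scheme32):
        study = self._study(scheme32)
        study.mask[:] = False
        with pytest.raises(ValueError, match="empty mask"):
            dti_core.normalize(study)


class TestOutlierCounts:
    def test_noiseless_phantom_has_no_outliers(self, clean_phantom):
        study, _ = clean_phantom
        fit = dti_core.fit_study(study)
        counts = dti_core.outlier_voxels_per_dwi(fit, study.b0, noise_sigma=10.0)
        assert counts.shape == (study.scheme.J,)
        assert counts.sum() == 0

    def test_zeroed_gradient_dominates_counts(self, clean_phantom):
        study, _ = clean_phantom
        dwis = study.dwis.copy()
        dwis[..., 5] = 0.0
        corrupted = DwiStudy(
            b0=study.b0, dwis=dwis, mask=study.mask, scheme=study.scheme,
            labels=study.labels,
        )
        fit = dti_core.fit_study(corrupted)
        # threshold at the phantom's operating noise level (sigma = 40)
        counts = dti_core.outlier_voxels_per_dwi(fit, study.b0, noise_sigma=40.0)
        others = np.delete(counts, 5)
        assert counts[5] > 10 * max(others.max(), 1)
        assert counts[5] == counts.max()

    def test_infinite_threshold_gives_zero(self, noisy_fit, noisy_phantom):
        study, _ = noisy_phantom
        counts = dti_core.outlier_voxels_per_dwi(
            noisy_fit, study.b0, noise_sigma=40.0, threshold=np.inf
        )
        assert counts.sum() == 0

    def test_nonpositive_sigma_rejected(self, noisy_fit, noisy_phantom):
        study, _ = noisy_phantom
        with pytest.raises(ValueError):
            dti_core.outlier_voxels_per_dwi(noisy_fit, study.b0, noise_sigma=0.0)
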
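"""Diffusion-tensor forward model, log-linear least-squares fitting and maps.

The single-tensor model relates the normalised signal along unit gradient
direction g_j at diffusion weighting b to the symmetric 3x3 tensor D:

    S_j = exp(-b g_j' D g_j)

Fitting is ordinary (unweighted) least squares on ln S_j, which is fast and
deterministic and is the estimator shared by the bootstrap and SIMEX Monte
Carlo paths.  Robust iterative fitting with outlier rejection is deliberately
not implemented; a residual-threshold outlier count per DWI stands in for it
in the QA report.

Tensor elements are stored in the order (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz),
units mm^2/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import DwiStudy, GradientScheme

logger = logging.getLogger(__name__)

#: column order of the six unique tensor elements
TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

_MAX_CONDITION = 1e8


@dataclass
class TensorFit:
    """Per-voxel tensor fit with eigensystem, scalar maps and residuals.

    Arrays are full-grid with NaN (or 0 for ``e1``) outside the analysis
    mask.  ``s_measured``/``s_fitted`` hold the normalised signals S_m / S_f
    for the in-mask voxels only, in the order given by ``mask_indices``.
    """

    tensors: np.ndarray        # (X, Y, Z, 6)
    eigenvalues: np.ndarray    # (X, Y, Z, 3), descending
    e1: np.ndarray             # (X, Y, Z, 3), unit principal eigenvector
    fa: np.ndarray             # (X, Y, Z) in [0, 1]
    md: np.ndarray             # (X, Y, Z) mm^2/s
    squared_error: np.ndarray  # (X, Y, Z): sum_j (S_m - S_f)^2
    mask: np.ndarray           # (X, Y, Z) bool analysis mask
    s_measured: np.ndarray     # (N, J)
    s_fitted: np.ndarray       # (N, J)
    scheme: GradientScheme
    affine: Optional[np.ndarray] = None

    @property
    def mask_indices(self) -> np.ndarray:
        """(N, 3) voxel coordinates of the in-mask voxels, C order."""
        return np.argwhere(self.mask)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(J, 6) matrix A with ln S = A d for tensor elements d."""
    g = scheme.directions
    return -scheme.b_value * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def tensor_to_matrix(d6: np.ndarray) -> np.ndarray:
    """Expand (..., 6) element vectors to (..., 3, 3) symmetric matrices."""
    d6 = np.asarray(d6, dtype=float)
    out = np.empty(d6.shape[:-1] + (3, 3))
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def matrix_to_tensor(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
         m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


def forward_signal(d6: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """Noiseless normalised signals S_j = exp(-b g_j' D g_j), shape (..., J)."""
    A = design_matrix(scheme)
    return np.exp(np.asarray(d6, dtype=float) @ A.T)


def eigvals_sym3(d6: np.ndarray) -> np.ndarray:
    """Closed-form eigenvalues of symmetric 3x3 tensors, descending.

    Trigonometric solution of the characteristic cubic; fully vectorised over
    leading axes, which keeps the bootstrap/SIMEX refit loops off LAPACK.
    """
    d6 = np.asarray(d6, dtype=float)
    a, b, c = d6[..., 0], d6[..., 1], d6[..., 2]
    d, e, f = d6[..., 3], d6[..., 4], d6[..., 5]
    q = (a + b + c) / 3.0
    p2 = (a - q) ** 2 + (b - q) ** 2 + (c - q) ** 2 + 2.0 * (d * d + e * e + f * f)
    p = np.sqrt(np.maximum(p2, 0.0) / 6.0)
    safe_p = np.where(p > 0, p, 1.0)
    aa, bb, cc = (a - q) / safe_p, (b - q) / safe_p, (c - q) / safe_p
    dd, ee, ff = d / safe_p, e / safe_p, f / safe_p
    detB = aa * (bb * cc - ff * ff) - dd * (dd * cc - ff * ee) + ee * (dd * ff - bb * ee)
    r = np.clip(detB / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    lam1 = q + 2.0 * p * np.cos(phi)
    lam3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    lam2 = 3.0 * q - lam1 - lam3
    return np.stack([lam1, lam2, lam3], axis=-1)


def fa_from_eigvals(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues.

    Negative eigenvalues (noise excursions) are clamped at zero before the
    ratio, and the result is clipped to [0, 1]; FA of the zero tensor is 0.
    """
    lam = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(num / den)
    return np.clip(np.where(den > 0, fa, 0.0), 0.0, 1.0)


def fa_md_from_tensors(d6: np.ndarray) -> tuple:
    """(FA, MD) for (..., 6) tensors via the closed-form eigensolver.

    MD is the plain eigenvalue mean (trace/3) without clamping; FA follows the
    clamped convention of :func:`fa_from_eigvals`.
    """
    evals = eigvals_sym3(d6)
    return fa_from_eigvals(evals), evals.mean(axis=-1)


def clamp_signals(s: np.ndarray) -> np.ndarray:
    """Replace non-positive / non-finite signals prior to the log transform.

    Each offending entry becomes half the smallest positive value in its own
    J-vector; a vector with no positive entry at all becomes a tiny constant.
    """
    s = np.asarray(s, dtype=float)
    bad = ~np.isfinite(s) | (s <= 0)
    if not bad.any():
        return s
    s = s.copy()
    masked = np.where(bad, np.inf, s)
    minpos = masked.min(axis=-1, keepdims=True)
    minpos = np.where(np.isfinite(minpos), minpos, 2e-8)
    return np.where(bad, 0.5 * minpos, s)


def normalize(study: DwiStudy) -> tuple:
    """Normalise DWIs by the b0 volume: S_m = DWI_j / b0, voxelwise.

    Returns ``(s_m, analysis_mask)`` where ``s_m`` is (N, J) over the in-mask
    voxels of ``analysis_mask`` (C order).  In-mask voxels with b0 <= 0 are
    excluded from the analysis mask; values above 1 are permitted (noise) but
    counted in the log.
    """
    if not study.mask.any():
        raise ValueError("empty mask: no voxels to analyse")
    analysis_mask = study.mask & (study.b0 > 0)
    n_dropped = int(study.mask.sum() - analysis_mask.sum())
    if n_dropped:
        logger.warning("dropped %d in-mask voxels with b0 <= 0", n_dropped)
    if not analysis_mask.any():
        raise ValueError("no in-mask voxels with positive b0")
    s_m = study.dwis[analysis_mask] / study.b0[analysis_mask][:, None]
    n_over = int((s_m > 1).sum())
    if n_over:
        logger.info("%d normalised signals exceed 1 (noise)", n_over)
    return s_m, analysis_mask


def fit_tensor_lls(s_m: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """Fit tensors by ordinary least squares on ln S, vectorised over voxels.

    Parameters
    ----------
    s_m : (..., J) ndarray
        Normalised signals; non-positive entries are clamped first.

    Returns
    -------
    (..., 6) ndarray of tensor elements.
    """
    A = design_matrix(scheme)
    cond = np.linalg.cond(A)
    if cond > _MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"degenerate gradient table: design condition number {cond:.3g}"
        )
    pinv = np.linalg.pinv(A)  # (6, J)
    s = clamp_signals(np.asarray(s_m, dtype=float))
    return np.log(s) @ pinv.T


def scalar_maps(
    d6: np.ndarray,
    mask: np.ndarray,
    s_m: np.ndarray,
    scheme: GradientScheme,
    affine: Optional[np.ndarray] = None,
) -> TensorFit:
    """Eigendecompose fitted tensors and assemble the full :class:`TensorFit`.

    ``d6`` and ``s_m`` are (N, 6) / (N, J) over the in-mask voxels in C order.
    Eigenvalues are sorted descending; the principal eigenvector's sign is
    fixed so its largest-magnitude component is positive (first coordinate
    wins ties), making e1 reproducible under eigenvalue degeneracy.
    """
    d6 = np.asarray(d6, dtype=float)
    mats = tensor_to_matrix(d6)
    evals, evecs = np.linalg.eigh(mats)       # ascending
    evals = evals[..., ::-1]
    e1 = evecs[..., :, ::-1][..., :, 0]       # eigenvector of largest eigenvalue
    # deterministic sign: largest-|component| positive, ties to lower index
    idx = np.abs(e1).argmax(axis=-1)
    lead = np.take_along_axis(e1, idx[..., None], axis=-1)[..., 0]
    sign = np.where(lead < 0, -1.0, 1.0)
    e1 = e1 * sign[..., None]

    fa = fa_from_eigvals(evals)
    md = evals.mean(axis=-1)
    s_f = forward_signal(d6, scheme)
    sq_err = ((s_m - s_f) ** 2).sum(axis=-1)

    shape = mask.shape

    def _full(values, ncomp=None, fill=np.nan):
        if ncomp is None:
            out = np.full(shape, fill)
            out[mask] = values
        else:
            out = np.full(shape + (ncomp,), fill)
            out[mask] = values
        return out

    return TensorFit(
        tensors=_full(d6, 6),
        eigenvalues=_full(evals, 3),
        e1=_full(e1, 3, fill=0.0),
        fa=_full(fa),
        md=_full(md),
        squared_error=_full(sq_err),
        mask=np.asarray(mask, dtype=bool),
        s_measured=np.asarray(s_m, dtype=float),
        s_fitted=s_f,
        scheme=scheme,
        affine=affine,
    )


def fit_study(study: DwiStudy) -> TensorFit:
    """Convenience path: normalise, fit and map a whole study."""
    s_m, analysis_mask = normalize(study)
    d6 = fit_tensor_lls(s_m, study.scheme)
    return scalar_maps(d6, analysis_mask, s_m, study.scheme, affine=study.affine)


def outlier_voxels_per_dwi(
    fit: TensorFit,
    b0: np.ndarray,
    noise_sigma: float,
    threshold: float = 3.0,
) -> np.ndarray:
    """In-mask voxels per DWI whose residual exceeds ``threshold`` sigma.

    A voxel-DWI pair is an outlier when |S_m - S_f| * b0 > threshold * sigma,
    i.e. the residual on the un-normalised intensity scale exceeds a multiple
    of the image noise.  This residual count is this package's own stand-in
    for robust-fit outlier maps and is labelled as such in the report.
    """
    if not noise_sigma > 0:
        raise ValueError(f"noise_sigma must be positive, got {noise_sigma}")
    resid = np.abs(fit.s_measured - fit.s_fitted) * np.asarray(b0)[fit.mask][:, None]
    return (resid > threshold * noise_sigma).sum(axis=0)
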
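"""Goodness-of-fit surfaces: pixel and slice chi-squared statistics.

The pixel chi-squared normalises each squared residual by the measured signal
itself rather than by a variance estimate, which maps both poor fits and high
noise to large values:

    chi2_pix(k) = sum_j ((S_m,jk - S_f,jk) / S_m,jk)^2        (one per voxel)

The slice adaptation sums the same normalised terms over the K in-mask voxels
of one axial slice of one DWI, rescaled by J/K so values remain comparable to
the per-voxel statistic regardless of slice size:

    chi2_slice(z, j) = (J / K) * sum_k ((S_m,jk - S_f,jk) / S_m,jk)^2

Values cluster into a "signal lobe" just above zero and a "noise lobe" near
0.2; 0.2 is rendered as saturation in the report's fixed display range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .dti_core import TensorFit

#: fixed display range of the slice chi-squared heatmap; 0.2 saturates
DISPLAY_RANGE = (0.0, 0.2)

_EPS = 1e-6


@dataclass
class ChiSquareMaps:
    """Per-voxel and per-slice-per-DWI chi-squared surfaces."""

    chi_pix: np.ndarray    # (X, Y, Z), NaN outside mask
    chi_slice: np.ndarray  # (n_axial_slices, J), NaN where K = 0
    display_range: Tuple[float, float] = DISPLAY_RANGE


def _normalized_sq_terms(s_m: np.ndarray, s_f: np.ndarray) -> np.ndarray:
    s_m = np.asarray(s_m, dtype=float)
    s_f = np.asarray(s_f, dtype=float)
    denom = np.maximum(np.abs(s_m), _EPS)
    return ((s_m - s_f) / denom) ** 2


def chi_pixel(s_m: np.ndarray, s_f: np.ndarray) -> np.ndarray:
    """Pixel chi-squared, vectorised over leading axes of (..., J) signals.

    The denominator is floored at 1e-6 to avoid blow-ups at signal voids; a
    voxel whose measured signals are all zero yields NaN (missing), not 0.
    """
    terms = _normalized_sq_terms(s_m, s_f)
    out = terms.sum(axis=-1)
    all_zero = (np.asarray(s_m) == 0).all(axis=-1)
    return np.where(all_zero, np.nan, out)


def chi_slice_matrix(fit: TensorFit) -> np.ndarray:
    """Full (n_axial_slices, J) slice chi-squared matrix for one study.

    Rows with no in-mask voxels are NaN, which render as the blank band seen
    above/below the brain in the heatmap.
    """
    terms = _normalized_sq_terms(fit.s_measured, fit.s_fitted)  # (N, J)
    z_of_voxel = fit.mask_indices[:, 2]
    n_slices = fit.mask.shape[2]
    J = fit.scheme.J
    out = np.full((n_slices, J), np.nan)
    sums = np.zeros((n_slices, J))
    np.add.at(sums, z_of_voxel, terms)
    counts = np.bincount(z_of_voxel, minlength=n_slices).astype(float)
    has = counts > 0
    out[has] = (J / counts[has, None]) * sums[has]
    return out


def chi_slice(fit: TensorFit, z: int, j: int) -> float:
    """Slice chi-squared for one (axial slice, DWI) pair; NaN when K = 0."""
    return float(chi_slice_matrix(fit)[z, j])


@dataclass
class ChiHistogram:
    counts: np.ndarray
    bin_edges: np.ndarray
    zoom_window: Tuple[float, float]
    signal_mode: float
    noise_mode: float


def chi_histogram(
    chi_pix: np.ndarray, bins: int = 100, zoom_percentile: float = 95.0
) -> ChiHistogram:
    """Histogram of in-mask pixel chi-squared with a noise-lobe zoom window.

    The magnification window is [P, max] where P is the ``zoom_percentile``
    of the finite values: the bulk of voxels sit in the signal lobe, so the
    upper tail isolates the noise lobe.  The signal mode is the peak of the
    full histogram; the noise mode is the peak within the zoom window.
    """
    vals = np.asarray(chi_pix, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 100:
        raise ValueError(f"need at least 100 in-mask voxels, got {vals.size}")
    counts, edges = np.histogram(vals, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    signal_mode = float(centers[np.argmax(counts)])
    lo = float(np.percentile(vals, zoom_percentile))
    hi = float(vals.max())
    tail = vals[vals >= lo]
    if tail.size and hi > lo:
        tcounts, tedges = np.histogram(tail, bins=min(bins, max(tail.size // 5, 1)))
        tcenters = 0.5 * (tedges[:-1] + tedges[1:])
        noise_mode = float(tcenters[np.argmax(tcounts)])
    else:
        noise_mode = signal_mode
    return ChiHistogram(
        counts=counts,
        bin_edges=edges,
        zoom_window=(lo, hi),
        signal_mode=signal_mode,
        noise_mode=noise_mode,
    )


def best_worst_slices(
    chi_slice_mat: np.ndarray, n_bands: int = 5, n_each: int = 5
) -> List[dict]:
    """Best/worst (z, j) slice pairs within each axial band of the brain.

    The axial extent with any finite entry is split into ``n_bands``
    contiguous bands (default fifths); within each band the ``n_each`` lowest
    and highest finite chi-squared entries are returned, ties broken by
    (z, j) order.  Bands with fewer than ``n_each`` finite entries return
    what exists and are flagged short.
    """
    mat = np.asarray(chi_slice_mat, dtype=float)
    finite_rows = np.where(np.isfinite(mat).any(axis=1))[0]
    if finite_rows.size == 0:
        raise ValueError("chi_slice matrix has no finite entries")
    z_lo, z_hi = finite_rows.min(), finite_rows.max()
    edges = np.linspace(z_lo, z_hi + 1, n_bands + 1)
    out = []
    for b in range(n_bands):
        zs = np.arange(int(np.floor(edges[b])), int(np.floor(edges[b + 1])))
        zs = zs[(zs >= z_lo) & (zs <= z_hi)]
        entries = []
        for z in zs:
            for j in range(mat.shape[1]):
                if np.isfinite(mat[z, j]):
                    entries.append((mat[z, j], z, j))
        entries.sort(key=lambda t: (t[0], t[1], t[2]))
        best = [(z, j) for _, z, j in entries[:n_each]]
        worst_sorted = sorted(entries, key=lambda t: (-t[0], t[1], t[2]))
        worst = [(z, j) for _, z, j in worst_sorted[:n_each]]
        out.append(
            {
                "band": b,
                "z_range": (int(zs.min()), int(zs.max())) if zs.size else None,
                "best": best,
                "worst": worst,
                "short": len(entries) < n_each,
            }
        )
    return out


def compute_gof(fit: TensorFit) -> ChiSquareMaps:
    """Pixel and slice chi-squared maps for one fitted study."""
    pix = np.full(fit.mask.shape, np.nan)
    pix[fit.mask] = chi_pixel(fit.s_measured, fit.s_fitted)
    return ChiSquareMaps(chi_pix=pix, chi_slice=chi_slice_matrix(fit))
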
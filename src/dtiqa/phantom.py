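"""Synthetic DTI phantom with known ground truth.

The phantom emulates a clinical single-shell brain acquisition: a
piecewise-constant tensor field over 25 labelled regions inside an
ellipsoidal "brain" mask, forward-simulated through the single-tensor signal
model, corrupted by a stacked Rician noise model (independent Rician noise on
the b0 and on each DWI), with optional injected artifacts (per-gradient
signal dropout, per-slice intensity offsets, synthetic motion rows).

Default conditions mirror a paediatric 3T protocol: b = 700 s/mm^2, 32
gradient directions, and SNR (b0 intensity over noise sigma) of 25.  Region
tensors span FA 0.1-0.9 and MD (0.6-3.0)e-3 mm^2/s so the regional boxplots
exercise their display ranges: anisotropic white-matter-like regions and
isotropic gray-matter-like regions.  The label scheme is 11 left/right
bilateral pairs (labels 1..22; odd = left, even = right) plus 3 midline
regions (labels 23..25), which pools to 14 regions for the QA feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dti_core import forward_signal, tensor_to_matrix, matrix_to_tensor
from .io_formats import DwiStudy, GradientScheme, MOTION_COLUMNS

N_REGIONS_DEFAULT = 25
N_BILATERAL_PAIRS = 11
N_MIDLINE = 3


@dataclass
class GradientDropout:
    """Multiply one DWI volume by ``factor`` (0 = complete signal loss)."""

    j: int
    factor: float = 0.0


@dataclass
class SliceArtifact:
    """Add ``offset`` image units to axial slice ``z`` of DWI ``j``."""

    z: int
    j: int
    offset: float


@dataclass
class MotionRow:
    """Synthetic motion-parameter entry for DWI ``j`` (registration metadata)."""

    j: int
    tx_mm: float = 0.0
    ty_mm: float = 0.0
    tz_mm: float = 0.0
    rx_deg: float = 0.0
    ry_deg: float = 0.0
    rz_deg: float = 0.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic study.

    noise_sigma is the Rician sigma in image units; with the default
    b0_intensity of 1000 the default sigma of 40 gives SNR 25, a typical
    clinical operating point.
    """

    grid_shape: Tuple[int, int, int] = (32, 32, 32)
    n_regions: int = N_REGIONS_DEFAULT
    b_value: float = 700.0
    n_gradients: int = 32
    directions: Optional[np.ndarray] = None
    region_tensors: Optional[np.ndarray] = None  # (R, 6)
    noise_sigma: float = 40.0
    b0_intensity: float = 1000.0
    voxel_size: Tuple[float, float, float] = (2.5, 2.5, 2.5)
    seed: int = 0
    artifacts: List = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Noise-free truth the QA metrics are validated against."""

    region_tensors: np.ndarray  # (R, 6)
    fa: np.ndarray              # (X, Y, Z)
    md: np.ndarray
    e1: np.ndarray              # (X, Y, Z, 3)
    sigma: float
    labels: np.ndarray


def electrostatic_directions(n: int, seed: int = 0, n_iter: int = 300) -> np.ndarray:
    """Quasi-uniform unit directions by electrostatic (Coulomb) repulsion.

    Antipodal symmetry is respected: each point repels both every other point
    and its antipode, as appropriate for diffusion encoding where g and -g are
    equivalent.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]
            dist2 = (diff**2).sum(axis=-1)
            np.fill_diagonal(dist2, np.inf)
            dist2 = np.maximum(dist2, 1e-12)
            force += (diff / dist2[..., None] ** 1.5).sum(axis=1)
        # project force onto the tangent plane and take a small step
        force -= (force * x).sum(axis=1, keepdims=True) * x
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        x = x + step * force / np.maximum(norm.max(), 1e-12)
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def tensor_from_fa_md(fa: float, md: float, direction: Sequence[float]) -> np.ndarray:
    """Axially symmetric tensor with given FA, MD and principal direction.

    With lambda_1 = MD(1 + 2a), lambda_2 = lambda_3 = MD(1 - a) one gets
    FA = 3a / sqrt(3 + 6a^2), inverted here for a.
    """
    if not 0 <= fa < 1:
        raise ValueError("fa must be in [0, 1)")
    if md <= 0:
        raise ValueError("md must be positive")
    a = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    lam = md * np.array([1 + 2 * a, 1 - a, 1 - a])
    v1 = np.asarray(direction, dtype=float)
    v1 = v1 / np.linalg.norm(v1)
    # complete an orthonormal frame
    helper = np.array([1.0, 0.0, 0.0])
    if abs(v1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v2 = np.cross(v1, helper)
    v2 /= np.linalg.norm(v2)
    v3 = np.cross(v1, v2)
    R = np.column_stack([v1, v2, v3])
    D = R @ np.diag(lam) @ R.T
    return matrix_to_tensor(D)


def default_region_tensors(n_regions: int, seed: int = 0) -> np.ndarray:
    """Ground-truth tensors spanning FA 0.1-0.9 and MD (0.6-3.0)e-3 mm^2/s.

    Bilateral pairs share a tensor (left/right symmetry), with principal
    directions rotating across pairs; midline regions are isotropic to
    CSF-like, mimicking gray matter / ventricles.
    """
    rng = np.random.default_rng(seed)
    n_pairs = N_BILATERAL_PAIRS
    tensors = np.zeros((n_regions, 6))
    fa_vals = np.linspace(0.9, 0.1, n_pairs)
    md_vals = np.linspace(0.6e-3, 1.2e-3, n_pairs)
    for p in range(n_pairs):
        theta = 2 * np.pi * p / n_pairs
        direction = np.array([np.cos(theta), np.sin(theta), 0.4])
        direction += 0.05 * rng.standard_normal(3)
        t = tensor_from_fa_md(fa_vals[p], md_vals[p], direction)
        left, right = 2 * p, 2 * p + 1
        if left < n_regions:
            tensors[left] = t
        if right < n_regions:
            tensors[right] = t
    md_mid = np.linspace(0.8e-3, 3.0e-3, max(n_regions - 2 * n_pairs, 1))
    for i, r in enumerate(range(2 * n_pairs, n_regions)):
        tensors[r] = tensor_from_fa_md(0.05 * (i + 1), md_mid[i], [0, 0, 1.0])
    return tensors


def build_labels(grid_shape: Tuple[int, int, int], n_regions: int = 25) -> np.ndarray:
    """Ellipsoidal brain mask tiled into labelled regions.

    Midline regions occupy a central left-right slab split into axial thirds;
    each hemisphere is cut into equal-count axial bands (quantiles of z), so
    every region is contiguous-ish and well populated on small grids.
    """
    nx, ny, nz = grid_shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    rx, ry, rz = 0.46 * nx, 0.46 * ny, 0.46 * nz
    mask = ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0

    def _rank_bands(zs: np.ndarray, n_bands: int) -> np.ndarray:
        """Equal-count contiguous bands along z (rank-based, never empty)."""
        order = np.argsort(zs, kind="stable")
        band = np.empty(zs.size, dtype=int)
        band[order] = (np.arange(zs.size) * n_bands) // zs.size
        return band

    if n_regions != N_REGIONS_DEFAULT:
        # generic fallback: equal-count axial bands over the whole mask
        labels = np.zeros(grid_shape, dtype=int)
        labels[mask] = _rank_bands(Z[mask], n_regions) + 1
        return labels

    labels = np.zeros(grid_shape, dtype=int)
    half_width = max(nx / 16.0, 1.0)
    midline = mask & (np.abs(X - cx) < half_width)
    left = mask & (X - cx <= -half_width)
    right = mask & (X - cx >= half_width)

    # 3 midline regions: axial thirds
    labels[midline] = 2 * N_BILATERAL_PAIRS + 1 + _rank_bands(Z[midline], N_MIDLINE)

    # 11 axial bands per hemisphere: odd labels left, even labels right
    for hemi_mask, offset in ((left, 1), (right, 2)):
        labels[hemi_mask] = 2 * _rank_bands(Z[hemi_mask], N_BILATERAL_PAIRS) + offset
    return labels


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    """Magnitude of a complex Gaussian-corrupted signal."""
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    real = signal + rng.normal(0.0, sigma, size=np.shape(signal))
    imag = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.hypot(real, imag)


def default_motion_table(J: int) -> pd.DataFrame:
    return pd.DataFrame(
        {"dwi_index": np.arange(1, J + 1)}
        | {c: np.zeros(J) for c in MOTION_COLUMNS[1:]}
    )


def generate(spec: PhantomSpec) -> Tuple[DwiStudy, GroundTruth]:
    """Simulate one study from a :class:`PhantomSpec`.

    Noise-free intensities are b0_intensity * S_j from the forward model;
    Rician noise of the spec's sigma is applied independently to the b0 and
    every DWI (the "stacked" model); injected artifacts are applied after the
    noise.  Deterministic for a given spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    directions = spec.directions
    if directions is None:
        # protocol (gradient table) is part of the ground truth, so its seed
        # is fixed: different phantom seeds redraw only the noise
        directions = electrostatic_directions(spec.n_gradients, seed=0)
    scheme = GradientScheme(b_value=spec.b_value, directions=directions)

    labels = build_labels(spec.grid_shape, spec.n_regions)
    mask = labels > 0
    region_ids = np.arange(1, spec.n_regions + 1)
    counts = np.bincount(labels.ravel(), minlength=spec.n_regions + 1)[1:]
    if np.any(counts == 0):
        empty = region_ids[counts == 0]
        raise ValueError(f"regions with zero voxels: {empty.tolist()}")

    tensors = spec.region_tensors
    if tensors is None:
        tensors = default_region_tensors(spec.n_regions)
    tensors = np.asarray(tensors, dtype=float)
    if tensors.shape != (spec.n_regions, 6):
        raise ValueError(f"region_tensors must be ({spec.n_regions}, 6)")

    region_signal = forward_signal(tensors, scheme)  # (R, J)
    J = scheme.J
    clean = np.zeros(spec.grid_shape + (J,))
    clean[mask] = spec.b0_intensity * region_signal[labels[mask] - 1]
    b0_clean = np.where(mask, spec.b0_intensity, 0.0)

    b0 = _rician(rng, b0_clean, spec.noise_sigma)
    dwis = _rician(rng, clean, spec.noise_sigma)

    motion = default_motion_table(J)
    for art in spec.artifacts:
        if isinstance(art, GradientDropout):
            dwis[..., art.j] *= art.factor
        elif isinstance(art, SliceArtifact):
            dwis[:, :, art.z, art.j] += art.offset
        elif isinstance(art, MotionRow):
            row = motion["dwi_index"] == art.j + 1
            for c in MOTION_COLUMNS[1:]:
                motion.loc[row, c] = getattr(art, c)
        else:
            raise TypeError(f"unknown artifact type: {art!r}")
    dwis = np.clip(dwis, 0.0, None)

    # ground-truth maps
    from .dti_core import fa_from_eigvals, eigvals_sym3

    evals = eigvals_sym3(tensors)
    fa_r = fa_from_eigvals(evals)
    md_r = evals.mean(axis=-1)
    mats = tensor_to_matrix(tensors)
    w, v = np.linalg.eigh(mats)
    e1_r = v[..., :, -1]
    idx = np.abs(e1_r).argmax(axis=-1)
    lead = np.take_along_axis(e1_r, idx[..., None], axis=-1)[..., 0]
    e1_r = e1_r * np.where(lead < 0, -1.0, 1.0)[..., None]

    fa_map = np.full(spec.grid_shape, np.nan)
    md_map = np.full(spec.grid_shape, np.nan)
    e1_map = np.zeros(spec.grid_shape + (3,))
    fa_map[mask] = fa_r[labels[mask] - 1]
    md_map[mask] = md_r[labels[mask] - 1]
    e1_map[mask] = e1_r[labels[mask] - 1]

    study = DwiStudy(
        b0=b0,
        dwis=dwis,
        mask=mask,
        scheme=scheme,
        voxel_size=np.asarray(spec.voxel_size),
        labels=labels,
        motion=motion,
    )
    truth = GroundTruth(
        region_tensors=tensors,
        fa=fa_map,
        md=md_map,
        e1=e1_map,
        sigma=spec.noise_sigma,
        labels=labels,
    )
    return study, truth


def generate_cohort(
    protocol_a: PhantomSpec,
    protocol_b: PhantomSpec,
    n_a: int,
    n_b: int,
    seed: int = 0,
    noise_scale: Optional[dict] = None,
) -> Tuple[list, pd.DataFrame]:
    """Simulate a two-protocol cohort with fresh per-study seeds.

    ``noise_scale`` maps cohort index -> multiplier on that member's noise
    sigma, used to plant known within-protocol quality outliers.  Returns the
    studies and a truth table recording protocol membership and the sigma
    actually used.
    """
    rng = np.random.default_rng(seed)
    noise_scale = noise_scale or {}
    studies = []
    rows = []
    specs = [protocol_a] * n_a + [protocol_b] * n_b
    names = ["A"] * n_a + ["B"] * n_b
    for i, (base, name) in enumerate(zip(specs, names)):
        scale = float(noise_scale.get(i, 1.0))
        member_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            grid_shape=base.grid_shape,
            n_regions=base.n_regions,
            b_value=base.b_value,
            n_gradients=base.n_gradients,
            directions=base.directions,
            region_tensors=base.region_tensors,
            noise_sigma=base.noise_sigma * scale,
            b0_intensity=base.b0_intensity,
            voxel_size=base.voxel_size,
            seed=member_seed,
            artifacts=list(base.artifacts),
        )
        study, truth = generate(spec)
        studies.append(study)
        rows.append(
            {
                "dataset": i,
                "protocol": name,
                "noise_sigma": spec.noise_sigma,
                "noise_scale": scale,
                "seed": member_seed,
            }
        )
    return studies, pd.DataFrame(rows)
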
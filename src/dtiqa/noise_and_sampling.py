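"""Regional noise estimation and voxel subsampling.

Noise is estimated from the segmented regions: for each region and each DWI
volume the standard deviation of the un-normalised intensities is computed,
the median across DWIs gives one estimate per region, and the second-smallest
regional estimate is taken as the image noise sigma.  The regional SD mixes
true noise with anatomical variability, so the smallest values are closest to
the noise floor; skipping the very smallest guards against a single
artifact-suppressed region.

Because the bootstrap and SIMEX estimators are Monte-Carlo expensive, only a
random subsample of in-mask voxels is evaluated, topped up per region until
every region contributes at least 50 sampled voxels (or all of a smaller
region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import DwiStudy

MIN_PER_REGION = 50
#: default sampled share of in-mask voxels; on grids emulating clinical
#: matrices this lands in the few-percent range typical for large datasets,
#: while the per-region floor drives small datasets toward tens of percent.
DEFAULT_TARGET_FRACTION = 0.04


@dataclass
class NoiseEstimate:
    regional_sds: np.ndarray  # (R,), image-intensity units, indexed by region order
    region_ids: np.ndarray    # (R,) label values the SDs belong to
    chosen_sigma: float       # second-smallest regional SD
    chosen_region: int        # label of the chosen region


@dataclass
class VoxelSample:
    indices: np.ndarray           # (n, 3) voxel coordinates
    regions: np.ndarray           # (n,) region label per sampled voxel
    per_region_counts: dict       # region label -> sampled count
    fraction: float               # sampled share of in-mask voxels


def estimate_noise(study: DwiStudy) -> NoiseEstimate:
    """Second-smallest of the per-region median-over-DWI signal SDs.

    SDs are population standard deviations of the raw DWI intensities over
    each region's voxels, computed per DWI volume (the b0 is excluded), then
    reduced by the median across volumes.
    """
    if study.labels is None:
        raise ValueError("noise estimation requires a region label volume")
    region_ids = study.region_ids
    if region_ids.size < 2:
        raise ValueError(
            f"need >= 2 labelled regions for the second-smallest rule, "
            f"got {region_ids.size}"
        )
    sds = np.empty(region_ids.size)
    for i, r in enumerate(region_ids):
        vox = study.dwis[study.labels == r]       # (n_r, J)
        sds[i] = np.median(vox.std(axis=0))       # median over DWIs
    order = np.argsort(sds, kind="stable")
    second = order[1]
    return NoiseEstimate(
        regional_sds=sds,
        region_ids=region_ids,
        chosen_sigma=float(sds[second]),
        chosen_region=int(region_ids[second]),
    )


def subsample_voxels(
    labels: np.ndarray,
    mask: np.ndarray,
    target_fraction: float = DEFAULT_TARGET_FRACTION,
    min_per_region: int = MIN_PER_REGION,
    seed: int = 0,
) -> VoxelSample:
    """Random in-mask voxel subsample with a per-region floor.

    First draws ``floor(target_fraction * n_in_mask)`` voxels uniformly
    without replacement across the mask, then tops up any region below
    ``min_per_region`` (or below its total size, if smaller) with additional
    random voxels from that region.  Deterministic for a given seed.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError(f"target_fraction must be in (0, 1], got {target_fraction}")
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool) & (labels > 0)
    rng = np.random.default_rng(seed)

    coords = np.argwhere(mask)
    n_mask = coords.shape[0]
    if n_mask == 0:
        raise ValueError("mask contains no labelled voxels")
    n_draw = int(np.floor(target_fraction * n_mask))
    chosen = np.zeros(n_mask, dtype=bool)
    if n_draw > 0:
        chosen[rng.choice(n_mask, size=n_draw, replace=False)] = True

    vox_labels = labels[mask]
    region_ids = np.unique(vox_labels)
    for r in region_ids:
        in_region = vox_labels == r
        need = min(min_per_region, int(in_region.sum()))
        have = int((chosen & in_region).sum())
        if have < need:
            pool = np.where(in_region & ~chosen)[0]
            extra = rng.choice(pool, size=need - have, replace=False)
            chosen[extra] = True

    idx = np.where(chosen)[0]
    sampled_labels = vox_labels[idx]
    counts = {int(r): int((sampled_labels == r).sum()) for r in region_ids}
    return VoxelSample(
        indices=coords[idx],
        regions=sampled_labels,
        per_region_counts=counts,
        fraction=idx.size / n_mask,
    )
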
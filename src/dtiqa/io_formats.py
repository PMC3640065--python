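"""Reading and writing of the standard on-disk formats the pipeline touches.

Volumes are NIfTI-1 (``.nii``/``.nii.gz``), gradient tables are FSL-dialect
``bval``/``bvec`` whitespace-separated text, motion parameters are TSV, and
tabular/scalar outputs are CSV/JSON.  All volumes are reoriented to RAS
(right-anterior-superior) on load so that axis 0 runs left->right, axis 1
posterior->anterior and axis 2 foot->head; axis 2 is the axial direction the
slice-wise statistics iterate over.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOTION_COLUMNS = ["dwi_index", "tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"]


class CorruptHeaderError(ValueError):
    """Gradient table or b-value information missing/unreadable."""


class StructuralError(ValueError):
    """Volume counts, shapes or labels do not agree with each other."""


class MissingB0Error(ValueError):
    """No non-diffusion-weighted volume present in the series."""


@dataclass
class GradientScheme:
    """Diffusion-encoding scheme: one b-value and J unit gradient directions.

    Parameters
    ----------
    b_value : float
        Diffusion weighting in s/mm^2; must be positive.
    directions : (J, 3) ndarray
        Unit gradient directions (the gradient table).  At least seven are
        required to determine the six tensor elements plus an intercept.
    """

    b_value: float
    directions: np.ndarray

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise StructuralError(
                f"directions must be (J, 3), got {self.directions.shape}"
            )
        if self.J < 7:
            raise StructuralError(
                f"need at least 7 gradient directions to fit a tensor, got {self.J}"
            )
        if not self.b_value > 0:
            raise CorruptHeaderError(f"b-value must be positive, got {self.b_value}")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise StructuralError("gradient directions must have unit norm (+-1e-6)")

    @property
    def J(self) -> int:
        """Number of diffusion-weighted volumes."""
        return self.directions.shape[0]


@dataclass
class DwiStudy:
    """One diffusion study: b0, J DWIs, mask and optional labels/motion.

    All volumes share one grid; axis 2 is axial (foot->head).  ``labels`` is an
    integer volume with 0 = background and 1..R = regions; when present it is
    restricted to in-mask voxels on construction.
    """

    b0: np.ndarray
    dwis: np.ndarray
    mask: np.ndarray
    scheme: GradientScheme
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    labels: Optional[np.ndarray] = None
    motion: Optional[pd.DataFrame] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.b0 = np.asarray(self.b0, dtype=float)
        self.dwis = np.asarray(self.dwis, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.b0.ndim != 3:
            raise StructuralError(f"b0 must be 3-D, got shape {self.b0.shape}")
        if self.dwis.ndim != 4:
            raise StructuralError(f"dwis must be 4-D, got shape {self.dwis.shape}")
        if self.dwis.shape[:3] != self.b0.shape or self.mask.shape != self.b0.shape:
            raise StructuralError("b0, dwis and mask must share one grid shape")
        if self.dwis.shape[3] != self.scheme.J:
            raise StructuralError(
                f"{self.dwis.shape[3]} DWI volumes but {self.scheme.J} gradient "
                "directions"
            )
        if np.any(self.dwis < 0):
            raise StructuralError("DWI intensities must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).astype(int)
            if self.labels.shape != self.b0.shape:
                raise StructuralError("labels grid does not match volumes")
            self.labels = np.where(self.mask, self.labels, 0)
        if self.affine is None:
            self.affine = np.diag(np.r_[self.voxel_size, 1.0])

    @property
    def grid_shape(self) -> tuple:
        return self.b0.shape

    @property
    def region_ids(self) -> np.ndarray:
        if self.labels is None:
            return np.array([], dtype=int)
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _load_ras(path) -> tuple:
    img = nib.as_closest_canonical(nib.load(str(path)))
    return np.asarray(img.dataobj, dtype=float), img.affine


def _read_bvecs(bvec_path) -> np.ndarray:
    try:
        raw = np.loadtxt(str(bvec_path))
    except OSError as exc:
        raise CorruptHeaderError(f"missing gradient table: {bvec_path}") from exc
    except ValueError as exc:
        raise CorruptHeaderError(f"unreadable gradient table: {bvec_path}") from exc
    if raw.ndim != 2:
        raise CorruptHeaderError(f"gradient table in {bvec_path} is not 2-D")
    if raw.shape[0] != 3 and raw.shape[1] == 3:
        raw = raw.T
    if raw.shape[0] != 3:
        raise CorruptHeaderError("bvec must have 3 rows (or 3 columns)")
    return raw.T  # (N, 3)


def load_study(
    dwi_path,
    bval_path,
    bvec_path,
    mask_path=None,
    labels_path=None,
    motion_path=None,
) -> DwiStudy:
    """Load a 4-D DWI series plus gradient table into a validated study.

    Zero rows of the bvec table mark b0 volumes; multiple b0 volumes are
    averaged into one.  All volumes are reoriented to RAS and gradient
    directions are renormalised to unit length.
    """
    data, affine = _load_ras(dwi_path)
    if data.ndim != 4:
        raise StructuralError(f"expected 4-D series, got shape {data.shape}")
    vecs = _read_bvecs(bvec_path)
    try:
        bvals = np.atleast_1d(np.loadtxt(str(bval_path), dtype=float))
    except OSError as exc:
        raise CorruptHeaderError(f"missing b-value file: {bval_path}") from exc
    if vecs.shape[0] != data.shape[3]:
        raise StructuralError(
            f"bvec lists {vecs.shape[0]} volumes but series has {data.shape[3]}"
        )
    if bvals.shape[0] != data.shape[3]:
        raise StructuralError(
            f"bval lists {bvals.shape[0]} volumes but series has {data.shape[3]}"
        )

    is_b0 = np.linalg.norm(vecs, axis=1) < 1e-8
    if not np.any(is_b0):
        raise MissingB0Error("no b0 volume (no zero gradient-table entry)")
    if np.all(is_b0):
        raise StructuralError("series contains only b0 volumes")
    b_nonzero = np.unique(bvals[~is_b0])
    if b_nonzero.size > 1:
        raise StructuralError(
            f"multiple diffusion weightings {b_nonzero}; single-shell data required"
        )

    b0 = data[..., is_b0].mean(axis=3)
    dwis = data[..., ~is_b0]
    directions = vecs[~is_b0]
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    scheme = GradientScheme(b_value=float(b_nonzero[0]), directions=directions)

    voxel_size = np.asarray(nib.affines.voxel_sizes(affine), dtype=float)
    mask = None
    if mask_path is not None:
        mask, _ = _load_ras(mask_path)
        mask = mask > 0.5
    else:
        mask = b0 > 0
    labels = None
    if labels_path is not None:
        labels, _ = _load_ras(labels_path)
        labels = np.rint(labels).astype(int)
    motion = None
    if motion_path is not None:
        motion = pd.read_csv(motion_path, sep="\t")
        missing = set(MOTION_COLUMNS) - set(motion.columns)
        if missing:
            raise StructuralError(f"motion table missing columns {sorted(missing)}")

    return DwiStudy(
        b0=b0,
        dwis=dwis,
        mask=mask,
        scheme=scheme,
        voxel_size=voxel_size,
        labels=labels,
        motion=motion,
        affine=affine,
    )


def save_study(study: DwiStudy, out_dir) -> dict:
    """Write a study back to NIfTI + bval/bvec (+ labels/mask/motion)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = study.affine
    series = np.concatenate([study.b0[..., None], study.dwis], axis=3)
    manifest = {}

    def _save(name, arr, dtype=np.float32):
        path = out / name
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine), str(path))
        manifest[name.split(".")[0]] = str(path)

    _save("dwi.nii.gz", series)
    _save("mask.nii.gz", study.mask, dtype=np.uint8)
    if study.labels is not None:
        _save("labels.nii.gz", study.labels, dtype=np.int16)

    bvecs = np.vstack([np.zeros(3), study.scheme.directions]).T
    np.savetxt(out / "dwi.bvec", bvecs, fmt="%.8f")
    bvals = np.r_[0.0, np.full(study.scheme.J, study.scheme.b_value)]
    np.savetxt(out / "dwi.bval", bvals[None, :], fmt="%.1f")
    manifest["bvec"] = str(out / "dwi.bvec")
    manifest["bval"] = str(out / "dwi.bval")
    if study.motion is not None:
        study.motion.to_csv(out / "motion.tsv", sep="\t", index=False)
        manifest["motion"] = str(out / "motion.tsv")
    return manifest


def save_outputs(fit, metrics, out_dir) -> dict:
    """Persist the stored pipeline outputs and return a file manifest.

    Scalar maps (FA, MD, squared error), the principal eigenvector, the
    six-component tensor field and the segmented b0 go to NIfTI; the noise
    estimate, sigma_FA/B_FA samples, power curves and the QA feature vector go
    to CSV/JSON.  Optional pieces absent from ``metrics`` are skipped and the
    omission is logged.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = getattr(fit, "affine", None)
    if affine is None:
        affine = np.eye(4)
    manifest = {}

    def _vol(name, arr, dtype=np.float32):
        path = out / f"{name}.nii.gz"
        try:
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine), str(path))
        except OSError as exc:
            raise OSError(f"failed writing {path}") from exc
        manifest[name] = str(path)

    _vol("fa", fit.fa)
    _vol("md", fit.md)
    _vol("squared_error", fit.squared_error)
    _vol("e1", fit.e1)
    _vol("tensor", fit.tensors)

    labels = getattr(metrics, "labels", None)
    if labels is not None:
        _vol("segmented_b0", labels, dtype=np.int16)

    def _csv(name, frame):
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest[name] = str(path)

    noise = getattr(metrics, "noise", None)
    if noise is not None:
        _csv(
            "noise_estimate",
            pd.DataFrame(
                {
                    "region": np.arange(1, len(noise.regional_sds) + 1),
                    "regional_sd": noise.regional_sds,
                }
            ),
        )
        (out / "noise_sigma.json").write_text(
            json.dumps(
                {
                    "chosen_sigma": float(noise.chosen_sigma),
                    "chosen_region": int(noise.chosen_region),
                }
            )
        )
        manifest["noise_sigma"] = str(out / "noise_sigma.json")

    sample_table = getattr(metrics, "sample_table", None)
    if sample_table is not None:
        _csv("uncertainty_samples", sample_table)
    else:
        logger.info("no sigma_FA/B_FA sample table; omitted from outputs")

    power = getattr(metrics, "power_curves", None)
    if power is not None:
        _csv("power_curves", power)
    else:
        logger.info("power curves not computed; omitted from outputs")

    chi_slice = getattr(metrics, "chi_slice", None)
    if chi_slice is not None:
        frame = pd.DataFrame(
            chi_slice,
            index=pd.RangeIndex(chi_slice.shape[0], name="axial_slice"),
            columns=[f"dwi_{j + 1}" for j in range(chi_slice.shape[1])],
        )
        frame.to_csv(out / "chi_slice.csv")
        manifest["chi_slice"] = str(out / "chi_slice.csv")

    feature_vector = getattr(metrics, "feature_vector", None)
    if feature_vector is not None:
        _csv("feature_vector", feature_vector)
    else:
        logger.info("QA feature vector not computed; omitted from outputs")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
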
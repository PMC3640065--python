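"""Regional QA summaries, the 112-element feature vector and cohort PCA.

Each dataset is reduced to per-region boxplot summaries of four metrics — MD,
FA, sigma_FA and B_FA — over both the full 25-region label set and a pooled
14-region set (11 bilateral pairs merged left+right, 3 midline regions kept).
Recording the mean and standard deviation of the underlying values for every
pooled region and metric gives 14 x 4 x 2 = 112 numbers per dataset, in a
canonical region-major order.

Across a cohort the vectors are column z-scored (constant columns dropped)
and embedded with SVD-based PCA; protocols separate into clusters in the
first two components, and robust within-group distances in score space flag
individual datasets as quality suspects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dti_core import TensorFit
from .phantom import N_BILATERAL_PAIRS, N_MIDLINE

METRICS = ("md", "fa", "sigma_fa", "bias_fa")
STATS = ("mean", "sd")
FEATURE_LENGTH = 112
OUTLIER_THRESHOLD = 3.5
_MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma for Gaussian data


def default_pooling_map() -> Dict[str, List[int]]:
    """Canonical 25 -> 14 pooling for the phantom label scheme.

    Labels 2p-1/2p (p = 1..11) are left/right partners of pair p; labels
    23..25 are midline.  Users with real label maps supply their own mapping
    (region name -> list of labels).
    """
    pooled = {
        f"pair_{p:02d}": [2 * p - 1, 2 * p] for p in range(1, N_BILATERAL_PAIRS + 1)
    }
    for m in range(1, N_MIDLINE + 1):
        pooled[f"mid_{m:02d}"] = [2 * N_BILATERAL_PAIRS + m]
    return pooled


@dataclass
class RegionalSummary:
    """Boxplot statistics per region per metric, full and pooled region sets.

    ``table`` columns: region_set ('full'|'pooled'), region (label int or
    pooled name), metric, n, mean, sd, median, q1, q3, whisker_lo,
    whisker_hi, n_outliers.  Whiskers follow the Tukey convention (most
    extreme points within 1.5 IQR of the box).
    """

    table: pd.DataFrame
    pooling: Dict[str, List[int]]


def _boxplot_row(values: np.ndarray) -> Optional[dict]:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return None
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=0)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "n_outliers": int(values.size - inside.size),
    }


def summarize_regions(
    fit: TensorFit,
    labels: np.ndarray,
    sample_table: pd.DataFrame,
    pooling: Optional[Dict[str, List[int]]] = None,
) -> RegionalSummary:
    """Per-region boxplot summaries of MD, FA, sigma_FA and B_FA.

    MD/FA are summarised over all in-mask voxels of each region; sigma_FA and
    B_FA over the sampled voxels only (``sample_table`` columns ``region``,
    ``sigma_fa``, ``bias_fa``).  Empty regions are logged as missing rows.
    """
    pooling = pooling or default_pooling_map()
    labels = np.asarray(labels)
    mask = fit.mask
    region_ids = np.unique(labels[labels > 0])

    vox_region = labels[mask]
    metric_vox = {"md": fit.md[mask], "fa": fit.fa[mask]}

    rows = []

    def _collect(region_set, region_name, label_list):
        in_set = np.isin(vox_region, label_list)
        for metric in ("md", "fa"):
            row = _boxplot_row(metric_vox[metric][in_set])
            if row is not None:
                rows.append(
                    {"region_set": region_set, "region": region_name,
                     "metric": metric, **row}
                )
        sel = sample_table["region"].isin(label_list)
        for metric, col in (("sigma_fa", "sigma_fa"), ("bias_fa", "bias_fa")):
            row = _boxplot_row(sample_table.loc[sel, col].to_numpy())
            if row is not None:
                rows.append(
                    {"region_set": region_set, "region": region_name,
                     "metric": metric, **row}
                )

    for r in region_ids:
        _collect("full", int(r), [int(r)])
    for name in sorted(pooling):
        _collect("pooled", name, pooling[name])

    return RegionalSummary(table=pd.DataFrame(rows), pooling=pooling)


@dataclass
class QaFeatureVector:
    values: np.ndarray          # canonical order, length 112 by default
    names: List[str]            # "<region>_<metric>_<stat>"
    dataset_id: str = ""
    protocol_id: str = ""


def build_feature_vector(
    summary: RegionalSummary,
    dataset_id: str = "",
    protocol_id: str = "",
    expected_length: Optional[int] = FEATURE_LENGTH,
) -> QaFeatureVector:
    """Canonical feature vector from the pooled regional summary.

    Order is region-major over the sorted pooled region names, then metric in
    (MD, FA, sigma_FA, B_FA), then (mean, sd).  Regions/metrics missing from
    the summary contribute NaN (imputed with cohort column means at embedding
    time).  Raises when the result length differs from ``expected_length``
    unless that check is disabled with ``expected_length=None``.
    """
    pooled = summary.table[summary.table["region_set"] == "pooled"]
    lookup = {
        (row["region"], row["metric"]): row for _, row in pooled.iterrows()
    }
    names, values = [], []
    for region in sorted(summary.pooling):
        for metric in METRICS:
            row = lookup.get((region, metric))
            for stat in STATS:
                names.append(f"{region}_{metric}_{stat}")
                values.append(float(row[stat]) if row is not None else np.nan)
    values = np.asarray(values)
    if expected_length is not None and values.size != expected_length:
        raise ValueError(
            f"feature vector has {values.size} elements, expected "
            f"{expected_length}; pass expected_length=None for custom region sets"
        )
    return QaFeatureVector(
        values=values, names=names, dataset_id=dataset_id, protocol_id=protocol_id
    )


@dataclass
class CohortEmbedding:
    zscored: np.ndarray            # (datasets, kept columns)
    scores: np.ndarray             # (datasets, n_components)
    loadings: np.ndarray           # (n_components, kept columns)
    explained_variance_ratio: np.ndarray
    kept_columns: np.ndarray       # indices into the original 112
    dropped_columns: np.ndarray    # constant columns removed before PCA
    dataset_ids: List[str]
    imputed: int                   # count of NaN cells replaced by column means


def embed_cohort(
    vectors: Sequence[QaFeatureVector], n_components: int = 2
) -> CohortEmbedding:
    """Z-score the cohort feature matrix and embed with SVD-based PCA.

    Constant columns (zero SD) are dropped and recorded; NaNs are imputed
    with the column mean first.  Component signs are fixed by making each
    loading's largest-magnitude entry positive, so the embedding is
    deterministic.
    """
    if len(vectors) < 3:
        raise ValueError(f"need at least 3 datasets, got {len(vectors)}")
    X = np.vstack([v.values for v in vectors]).astype(float)
    col_mean = np.nanmean(X, axis=0)
    nan_cells = ~np.isfinite(X)
    if nan_cells.any():
        X[nan_cells] = np.broadcast_to(col_mean, X.shape)[nan_cells]
    sd = X.std(axis=0, ddof=0)
    # constant columns up to float rounding: no information, would blow up z
    tol = 1e-12 * np.maximum(1.0, np.abs(X).mean(axis=0))
    kept = np.where(sd > tol)[0]
    dropped = np.where(sd <= tol)[0]
    if kept.size == 0:
        raise ValueError("all feature columns are constant across the cohort")
    Z = (X[:, kept] - X[:, kept].mean(axis=0)) / sd[kept]

    n_components = min(n_components, len(vectors) - 1, kept.size)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_
    for c in range(loadings.shape[0]):
        i = np.abs(loadings[c]).argmax()
        if loadings[c, i] < 0:
            loadings[c] *= -1
            scores[:, c] *= -1
    return CohortEmbedding(
        zscored=Z,
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        kept_columns=kept,
        dropped_columns=dropped,
        dataset_ids=[v.dataset_id for v in vectors],
        imputed=int(nan_cells.sum()),
    )


def flag_outliers(
    embedding: CohortEmbedding,
    groups: Sequence[str],
    threshold: float = OUTLIER_THRESHOLD,
    min_group_size: int = 4,
) -> pd.DataFrame:
    """Robust within-group outlier flags in PCA score space.

    Per group, each component of each score is reduced to a robust z value
    (distance from the group median scaled by 1.4826 * MAD); the Euclidean
    norm across components is the outlier score, flagged above ``threshold``.
    Groups smaller than ``min_group_size`` are skipped with a warning column.
    """
    groups = np.asarray(groups)
    if groups.size != embedding.scores.shape[0]:
        raise ValueError("group labels must match number of embedded datasets")
    rows = []
    for g in np.unique(groups):
        sel = groups == g
        pts = embedding.scores[sel]
        idx = np.where(sel)[0]
        if pts.shape[0] < min_group_size:
            for i in idx:
                rows.append(
                    {"dataset": i, "group": g, "score": np.nan,
                     "flagged": False, "skipped": True}
                )
            continue
        med = np.median(pts, axis=0)
        mad = np.median(np.abs(pts - med), axis=0)
        scale = np.where(mad > 0, _MAD_SCALE * mad, pts.std(axis=0, ddof=0))
        scale = np.where(scale > 0, scale, 1.0)
        rz = (pts - med) / scale
        dist = np.sqrt((rz**2).sum(axis=1))
        for i, d in zip(idx, dist):
            rows.append(
                {"dataset": int(i), "group": g, "score": float(d),
                 "flagged": bool(d > threshold), "skipped": False}
            )
    return pd.DataFrame(rows).sort_values("dataset").reset_index(drop=True)


def vectors_to_frame(vectors: Sequence[QaFeatureVector]) -> pd.DataFrame:
    """One row per dataset: id columns + the named feature values."""
    rows = []
    for v in vectors:
        row = {"dataset_id": v.dataset_id, "protocol_id": v.protocol_id}
        row.update(dict(zip(v.names, v.values)))
        rows.append(row)
    return pd.DataFrame(rows)
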
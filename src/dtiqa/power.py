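"""Bias-aware power curves for a two-sided two-sample t-test.

For two groups of size n with common standard deviation s and a between-group
bias difference Delta_B, the power to detect an effect size ES is computed
from the noncentral t distribution with df = 2n - 2 and noncentrality

    delta = (ES + Delta_B) / (s * sqrt(2 / n)):

    power = 1 - F_nct(t_crit; df, delta) + F_nct(-t_crit; df, delta)

where t_crit is the central-t (1 - alpha/2) quantile.  With Delta_B = 0 this
is the textbook two-sample power equation and equals alpha at ES = 0; a
nonzero bias difference shifts the curve minimum to ES = -Delta_B.  The
worst-case convention sets Delta_B equal to the voxel's own estimated FA bias
(comparison group assumed unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_N_LIST = (5, 15, 30)
#: 101-point effect-size grid in FA units
DEFAULT_ES_GRID = np.linspace(-0.1, 0.1, 101)


@dataclass
class PowerCurve:
    region: int
    n: int
    biased: bool
    es_grid: np.ndarray
    power: np.ndarray
    s: float          # median sigma_FA over the region's sampled voxels
    delta_b: float    # median bias over the region (0 for the unbiased curve)
    alpha_nom: float = DEFAULT_ALPHA

    @property
    def df(self) -> int:
        return 2 * self.n - 2


def _nct_cdf(x, df, nc):
    """Noncentral-t CDF with fallbacks for deep-tail NaNs.

    scipy's boost-backed ``nct.cdf`` can return NaN far out in a tail; those
    entries are recomputed via the symmetry F(x; nc) = 1 - F(-x; -nc) and,
    failing that, replaced by the saturated tail value implied by the sign of
    (x - nc).
    """
    x, df, nc = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(df, float), np.asarray(nc, float)
    )
    out = stats.nct.cdf(x, df, nc)
    bad = ~np.isfinite(out)
    if bad.any():
        out = np.where(bad, 1.0 - stats.nct.cdf(-x, df, -nc), out)
        bad = ~np.isfinite(out)
    if bad.any():
        out = np.where(bad, np.where(x < nc, 0.0, 1.0), out)
    return out


def power_two_sided_t(es, n, s, delta_b=0.0, alpha_nom=DEFAULT_ALPHA):
    """Power of the two-sided two-sample t-test at effect size ``es``.

    Vectorised over any broadcastable combination of arguments.  The
    degenerate limit s = 0 returns power 1 wherever es + delta_b != 0 and
    alpha_nom at the curve minimum.
    """
    es = np.asarray(es, dtype=float)
    n = np.asarray(n)
    s = np.asarray(s, dtype=float)
    delta_b = np.asarray(delta_b, dtype=float)
    if np.any(n < 2):
        raise ValueError("n must be >= 2")
    if not 0 < alpha_nom < 1:
        raise ValueError(f"alpha_nom must be in (0, 1), got {alpha_nom}")
    if np.any(s < 0):
        raise ValueError("s must be >= 0")

    df = 2 * n - 2
    t_crit = stats.t.ppf(1 - alpha_nom / 2, df)
    shift = es + delta_b
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = shift / (s * np.sqrt(2.0 / n))

    zero_nc = shift == 0
    # central case evaluated with the central t for exactness at the minimum
    central = 2 * stats.t.cdf(-t_crit, df)
    nc = np.where(np.isfinite(delta), delta, 0.0)
    noncentral = _nct_cdf(-t_crit, df, nc) + 1 - _nct_cdf(t_crit, df, nc)
    out = np.where(zero_nc, central, noncentral)
    out = np.where((s == 0) & ~zero_nc, 1.0, out)
    if np.ndim(out) == 0:
        return float(out)
    return out


def regional_power_curves(
    sigma_fa: np.ndarray,
    bias_fa: np.ndarray,
    regions: np.ndarray,
    region_ids: Sequence[int] | None = None,
    n_list: Sequence[int] = DEFAULT_N_LIST,
    es_grid: np.ndarray = DEFAULT_ES_GRID,
    alpha_nom: float = DEFAULT_ALPHA,
) -> list:
    """Median power curve per region per sample size, with and without bias.

    For every sampled voxel the analytic power is evaluated with that voxel's
    sigma_FA as s and delta_b in {0, B_FA}; the per-effect-size median across
    the region's sampled voxels is the regional curve.  Only voxels with both
    estimates enter.  Regions with no sampled voxels are skipped.
    """
    sigma_fa = np.asarray(sigma_fa, dtype=float)
    bias_fa = np.asarray(bias_fa, dtype=float)
    regions = np.asarray(regions)
    es_grid = np.asarray(es_grid, dtype=float)
    if region_ids is None:
        region_ids = np.unique(regions)

    curves = []
    for r in region_ids:
        sel = (regions == r) & np.isfinite(sigma_fa) & np.isfinite(bias_fa)
        if not sel.any():
            continue
        s_vox = sigma_fa[sel]
        b_vox = bias_fa[sel]
        ok = s_vox > 0
        if not ok.any():
            continue
        s_vox, b_vox = s_vox[ok], b_vox[ok]
        for n in n_list:
            for biased in (False, True):
                db = b_vox if biased else np.zeros_like(b_vox)
                pw = power_two_sided_t(
                    es_grid[None, :], n, s_vox[:, None], db[:, None], alpha_nom
                )
                curves.append(
                    PowerCurve(
                        region=int(r),
                        n=int(n),
                        biased=biased,
                        es_grid=es_grid,
                        power=np.median(pw, axis=0),
                        s=float(np.median(s_vox)),
                        delta_b=float(np.median(b_vox)) if biased else 0.0,
                        alpha_nom=alpha_nom,
                    )
                )
    return curves


def curves_to_frame(curves: Sequence[PowerCurve]) -> pd.DataFrame:
    """Tidy (region, n, biased, es, power) table for CSV export."""
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {
                    "region": c.region,
                    "n": c.n,
                    "biased": c.biased,
                    "es": c.es_grid,
                    "power": c.power,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["region", "n", "biased", "es", "power"])
    return pd.concat(rows, ignore_index=True)
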
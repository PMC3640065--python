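"""Four-page graphical QA report.

Page 1 — acquisition summary, motion traces, residual-outlier counts per DWI,
slice chi-squared heatmap and pixel chi-squared histogram (the four per-DWI
plots share one horizontally aligned DWI-index abscissa), plus best/worst
slice thumbnails per axial fifth.  Page 2 — region schematic and per-region
boxplots of MD, FA, sigma_FA and B_FA, with optional reference-cohort boxes.
Page 3 — mid-axial MD/FA maps, regional-median sigma_FA and B_FA maps, power
curves, and principal-eigenvector colour maps in three planes (R = right-left,
G = anterior-posterior, B = foot-head).  Page 4 — eigenvector line overlays
on the colour map at three magnifications.

Rendering is a pure function of the computed metrics: the same inputs produce
the same pages.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages

from .gof import DISPLAY_RANGE, best_worst_slices, chi_histogram

N_PAGES = 4
_FIGSIZE = (8.27, 11.69)  # A4 portrait


def _placeholder(ax, text):
    ax.text(0.5, 0.5, text, ha="center", va="center", fontsize=9, color="gray")
    ax.set_xticks([])
    ax.set_yticks([])


def _axial(img, z=None):
    """Mid-axial slice oriented with anterior up, patient left on image left."""
    if z is None:
        z = img.shape[2] // 2
    return np.asarray(img[:, :, z]).T


def e1_colormap(e1: np.ndarray, fa: np.ndarray) -> np.ndarray:
    """Direction-encoded RGB: channels |e1| scaled by FA.

    R = right-left (axis 0), G = anterior-posterior (axis 1),
    B = foot-head (axis 2).
    """
    fa = np.nan_to_num(np.asarray(fa, dtype=float), nan=0.0)
    rgb = np.abs(np.asarray(e1, dtype=float)) * fa[..., None]
    return np.clip(rgb, 0.0, 1.0)


def _page1(pdf, study, fit, metrics):
    fig = plt.figure(figsize=_FIGSIZE)
    gs = fig.add_gridspec(
        8,
        2,
        height_ratios=[0.9, 1, 1, 1, 2.2, 1.6, 1.1, 1.1],
        hspace=0.65,
        wspace=0.25,
    )

    ax = fig.add_subplot(gs[0, :])
    ax.axis("off")
    J = study.scheme.J
    info = (
        f"grid {study.grid_shape}   J = {J} gradients   "
        f"b = {study.scheme.b_value:.0f} s/mm$^2$   "
        f"voxel {tuple(np.round(study.voxel_size, 2))} mm"
    )
    noise = getattr(metrics, "noise", None)
    if noise is not None:
        info += f"   noise $\\hat\\sigma$ = {noise.chosen_sigma:.2f}"
    ax.text(0.0, 0.7, "DTI QA report", fontsize=14, weight="bold")
    ax.text(0.0, 0.25, info, fontsize=9)

    x = np.arange(1, J + 1)
    xlim = (0.5, J + 0.5)

    ax_t = fig.add_subplot(gs[1, :])
    ax_r = fig.add_subplot(gs[2, :])
    if study.motion is not None:
        m = study.motion
        for c in ("tx_mm", "ty_mm", "tz_mm"):
            ax_t.plot(m["dwi_index"], m[c], lw=0.8, label=c[:2])
        ax_t.legend(fontsize=6, ncol=3)
        for c in ("rx_deg", "ry_deg", "rz_deg"):
            ax_r.plot(m["dwi_index"], m[c], lw=0.8, label=c[:2])
        ax_r.legend(fontsize=6, ncol=3)
    else:
        _placeholder(ax_t, "motion parameters not available")
        _placeholder(ax_r, "motion parameters not available")
    ax_t.set_xlim(xlim)
    ax_t.set_ylabel("transl. (mm)", fontsize=7)
    ax_r.set_xlim(xlim)
    ax_r.set_ylabel("rot. (deg)", fontsize=7)

    ax_o = fig.add_subplot(gs[3, :])
    counts = getattr(metrics, "outlier_counts", None)
    if counts is not None:
        ax_o.bar(x, counts, width=0.8, color="tab:red")
        ax_o.set_ylabel("outlier voxels\n(>3$\\sigma$ residual)", fontsize=7)
    else:
        _placeholder(ax_o, "outlier counts not available")
    ax_o.set_xlim(xlim)

    ax_c = fig.add_subplot(gs[4, :])
    mat = metrics.chi_slice
    im = ax_c.imshow(
        mat,
        aspect="auto",
        origin="lower",
        vmin=DISPLAY_RANGE[0],
        vmax=DISPLAY_RANGE[1],
        extent=(0.5, J + 0.5, -0.5, mat.shape[0] - 0.5),
        cmap="jet",
        interpolation="nearest",
    )
    ax_c.set_xlim(xlim)
    ax_c.set_xlabel("DWI index", fontsize=8)
    ax_c.set_ylabel("axial slice", fontsize=8)
    fig.colorbar(im, ax=ax_c, fraction=0.03, label="$\\chi^2$ per slice")

    ax_h = fig.add_subplot(gs[5, 0])
    ax_z = fig.add_subplot(gs[5, 1])
    try:
        hist = chi_histogram(metrics.chi_pix)
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        ax_h.bar(centers, hist.counts, width=np.diff(hist.bin_edges), color="tab:blue")
        ax_h.set_xlabel("$\\chi^2_{pix}$", fontsize=8)
        lo, hi = hist.zoom_window
        vals = metrics.chi_pix[np.isfinite(metrics.chi_pix)]
        tail = vals[(vals >= lo) & (vals <= hi)]
        if tail.size and hi > lo:
            ax_z.hist(tail, bins=30, color="tab:orange")
        else:
            _placeholder(ax_z, "noise lobe empty")
        ax_z.set_xlabel(f"noise-lobe zoom [{lo:.3g}, {hi:.3g}]", fontsize=8)
    except ValueError as exc:
        _placeholder(ax_h, str(exc))
        _placeholder(ax_z, "")

    # best/worst DWI slice thumbnails per axial fifth
    try:
        bands = best_worst_slices(metrics.chi_slice)
    except ValueError:
        bands = []
    for row, kind in ((6, "best"), (7, "worst")):
        sub = gs[row, :].subgridspec(1, max(len(bands), 1), wspace=0.1)
        if not bands:
            _placeholder(fig.add_subplot(sub[0]), "no slice statistics")
            continue
        for i, band in enumerate(bands):
            ax = fig.add_subplot(sub[i])
            pairs = band[kind]
            if pairs:
                z, j = pairs[0]
                ax.imshow(_axial(study.dwis[..., j], z=z), cmap="gray",
                          origin="lower")
                ax.set_title(f"{kind} z={z} j={j + 1}", fontsize=6)
            else:
                _placeholder(ax, "none")
            ax.set_xticks([])
            ax.set_yticks([])
    pdf.savefig(fig)
    plt.close(fig)


def _region_boxes(ax, sub: pd.DataFrame, ref: Optional[pd.DataFrame], metric):
    regions = sub["region"].tolist()
    stats = [
        {
            "med": r["median"], "q1": r["q1"], "q3": r["q3"],
            "whislo": r["whisker_lo"], "whishi": r["whisker_hi"], "fliers": [],
        }
        for _, r in sub.iterrows()
    ]
    pos = np.arange(len(regions)) * 2.0
    ax.bxp(stats, positions=pos, widths=0.7, showfliers=False,
           boxprops={"color": "tab:blue"}, medianprops={"color": "tab:blue"})
    if ref is not None:
        rsub = ref[ref["metric"] == metric].set_index("region")
        rstats, rpos = [], []
        for i, reg in enumerate(regions):
            if reg in rsub.index:
                r = rsub.loc[reg]
                rstats.append(
                    {"med": r["median"], "q1": r["q1"], "q3": r["q3"],
                     "whislo": r["whisker_lo"], "whishi": r["whisker_hi"],
                     "fliers": []}
                )
                rpos.append(pos[i] + 0.8)
        if rstats:
            ax.bxp(rstats, positions=rpos, widths=0.5, showfliers=False,
                   boxprops={"color": "black"}, medianprops={"color": "black"})
    ax.set_xticks(pos)
    ax.set_xticklabels([str(r) for r in regions], fontsize=5, rotation=90)
    ax.set_ylabel(metric, fontsize=8)


def _page2(pdf, study, metrics, reference):
    fig = plt.figure(figsize=_FIGSIZE)
    gs = fig.add_gridspec(5, 4, hspace=0.6, wspace=0.3)

    ax = fig.add_subplot(gs[0, :2])
    if study.labels is not None:
        ax.imshow(_axial(study.labels), cmap="tab20", origin="lower",
                  interpolation="nearest")
        ax.set_title("segmented regions (mid-axial)", fontsize=8)
    else:
        _placeholder(ax, "labels not available")
    ax.set_xticks([])
    ax.set_yticks([])
    ax2 = fig.add_subplot(gs[0, 2:])
    ax2.axis("off")
    ax2.text(0, 0.8, "blue: this dataset", color="tab:blue", fontsize=8)
    if reference is not None:
        ax2.text(0, 0.6, "black: reference cohort", color="black", fontsize=8)
    else:
        ax2.text(0, 0.6, "reference cohort: not provided", color="gray", fontsize=8)

    summary = getattr(metrics, "regional_summary", None)
    for i, metric in enumerate(("md", "fa", "sigma_fa", "bias_fa")):
        ax = fig.add_subplot(gs[i + 1, :])
        if summary is None:
            _placeholder(ax, f"{metric}: regional summary not available")
            continue
        sub = summary.table[
            (summary.table["region_set"] == "full")
            & (summary.table["metric"] == metric)
        ]
        if sub.empty:
            _placeholder(ax, f"{metric}: not computed")
        else:
            _region_boxes(ax, sub, reference, metric)
    pdf.savefig(fig)
    plt.close(fig)


def _median_region_map(values: pd.DataFrame, labels, metric) -> np.ndarray:
    """Full-grid map holding each region's median metric value everywhere."""
    out = np.full(labels.shape, np.nan)
    sub = values[(values["region_set"] == "full") & (values["metric"] == metric)]
    for _, row in sub.iterrows():
        out[labels == row["region"]] = row["median"]
    return out


def _page3(pdf, study, fit, metrics):
    fig = plt.figure(figsize=_FIGSIZE)
    gs = fig.add_gridspec(4, 4, hspace=0.45, wspace=0.3)

    panels = [("MD", fit.md, "viridis"), ("FA", fit.fa, "gray")]
    summary = getattr(metrics, "regional_summary", None)
    if summary is not None and study.labels is not None:
        panels.append(
            ("median $\\sigma_{FA}$",
             _median_region_map(summary.table, study.labels, "sigma_fa"), "magma")
        )
        panels.append(
            ("median $B_{FA}$",
             _median_region_map(summary.table, study.labels, "bias_fa"), "magma")
        )
    for i, (title, img, cmap) in enumerate(panels):
        ax = fig.add_subplot(gs[0, i])
        kw = {"vmin": 0.0, "vmax": 1.0} if title == "FA" else {}
        ax.imshow(_axial(img), cmap=cmap, origin="lower", **kw)
        ax.set_title(title, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])

    ax_p = fig.add_subplot(gs[1, :2])
    ax_pb = fig.add_subplot(gs[1, 2:])
    curves = getattr(metrics, "power_curve_objects", None)
    if curves:
        colors = {5: "black", 15: "tab:red", 30: "tab:blue"}
        for c in curves:
            ax = ax_pb if c.biased else ax_p
            ax.plot(c.es_grid, c.power, color=colors.get(c.n, "gray"),
                    lw=1.0, label=f"n={c.n}")
        for ax, title in ((ax_p, "power (no bias)"), (ax_pb, "power (worst-case bias)")):
            ax.set_title(title, fontsize=8)
            ax.set_xlabel("effect size (FA)", fontsize=7)
            ax.set_ylim(0, 1.02)
            handles, labels_ = ax.get_legend_handles_labels()
            seen = dict(zip(labels_, handles))
            ax.legend(seen.values(), seen.keys(), fontsize=6)
    else:
        _placeholder(ax_p, "power curves not available")
        _placeholder(ax_pb, "power curves not available")

    rgb = e1_colormap(fit.e1, fit.fa)
    mid = [s // 2 for s in rgb.shape[:3]]
    views = [
        ("axial (R|G)", rgb[:, :, mid[2]].transpose(1, 0, 2)),
        ("coronal (R|B)", rgb[:, mid[1], :].transpose(1, 0, 2)),
        ("sagittal (G|B)", rgb[mid[0], :, :].transpose(1, 0, 2)),
    ]
    for i, (title, img) in enumerate(views):
        ax = fig.add_subplot(gs[2, i])
        ax.imshow(img, origin="lower", interpolation="nearest")
        ax.set_title(title, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    ax = fig.add_subplot(gs[2, 3])
    ax.axis("off")
    ax.text(0, 0.7, "R = right-left", color="red", fontsize=8)
    ax.text(0, 0.5, "G = anterior-posterior", color="green", fontsize=8)
    ax.text(0, 0.3, "B = foot-head", color="blue", fontsize=8)
    pdf.savefig(fig)
    plt.close(fig)


def _vector_overlay(ax, fit, plane, zoom):
    """In-plane e1 line segments over the colour map, one segment per voxel."""
    rgb = e1_colormap(fit.e1, fit.fa)
    mid = [s // 2 for s in rgb.shape[:3]]
    if plane == "axial":
        img = rgb[:, :, mid[2]].transpose(1, 0, 2)
        u = fit.e1[:, :, mid[2], 0].T
        v = fit.e1[:, :, mid[2], 1].T
        w = fit.fa[:, :, mid[2]].T
    else:  # coronal
        img = rgb[:, mid[1], :].transpose(1, 0, 2)
        u = fit.e1[:, mid[1], :, 0].T
        v = fit.e1[:, mid[1], :, 2].T
        w = fit.fa[:, mid[1], :].T
    ax.imshow(img, origin="lower", interpolation="nearest")
    ny, nx = u.shape
    cy, cx = ny // 2, nx // 2
    hy, hx = max(ny // (2 * zoom), 2), max(nx // (2 * zoom), 2)
    ys, xs = np.mgrid[cy - hy:cy + hy, cx - hx:cx + hx]
    ys, xs = ys.ravel(), xs.ravel()
    keep = (ys >= 0) & (ys < ny) & (xs >= 0) & (xs < nx)
    ys, xs = ys[keep], xs[keep]
    scale = 0.45
    for y, x in zip(ys, xs):
        f = w[y, x]
        if not np.isfinite(f) or f <= 0.05:
            continue
        dx, dy = u[y, x] * scale, v[y, x] * scale
        ax.plot([x - dx, x + dx], [y - dy, y + dy], color="white", lw=0.4)
    ax.set_xlim(cx - hx - 0.5, cx + hx - 0.5)
    ax.set_ylim(cy - hy - 0.5, cy + hy - 0.5)
    ax.set_xticks([])
    ax.set_yticks([])


def _page4(pdf, fit):
    fig = plt.figure(figsize=_FIGSIZE)
    gs = fig.add_gridspec(3, 2, hspace=0.3, wspace=0.15)
    for row, zoom in enumerate((1, 2, 4)):
        for col, plane in enumerate(("axial", "coronal")):
            ax = fig.add_subplot(gs[row, col])
            _vector_overlay(ax, fit, plane, zoom)
            if row == 0:
                ax.set_title(f"mid-{plane}", fontsize=9)
            if col == 0:
                ax.set_ylabel(f"zoom x{zoom}", fontsize=8)
    fig.suptitle("principal eigenvector overlay (white segments)", fontsize=10)
    pdf.savefig(fig)
    plt.close(fig)


def render_report(
    study,
    fit,
    metrics,
    out_path,
    reference: Optional[pd.DataFrame] = None,
) -> int:
    """Render the four-page PDF QA report; returns the page count.

    ``metrics`` must provide ``chi_pix`` and ``chi_slice``; everything else
    (motion, outlier counts, regional summary, power curves, noise estimate,
    reference cohort) is optional and replaced by labelled placeholders when
    absent.  ``reference`` is a boxplot-statistics table with columns
    region, metric, median, q1, q3, whisker_lo, whisker_hi.
    """
    for name in ("chi_pix", "chi_slice"):
        if getattr(metrics, name, None) is None:
            raise ValueError(f"missing mandatory metric: {name}")
    with PdfPages(str(out_path)) as pdf:
        _page1(pdf, study, fit, metrics)
        _page2(pdf, study, metrics, reference)
        _page3(pdf, study, fit, metrics)
        _page4(pdf, fit)
        n = pdf.get_pagecount()
    return n
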
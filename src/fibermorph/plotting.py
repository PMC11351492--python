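"""Figure output: width histograms, area histograms with fitted GPD
density overlays, and shape-scale scatter plots with CI rectangles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Rectangle
from scipy import stats

__all__ = ["plot_outputs", "k_sigma_axes"]

_GROUP_COLORS = ("tab:green", "tab:red", "tab:blue", "black")


def _width_histograms(report, out: Path) -> list[Path]:
    paths = []
    for gi, year in enumerate(report.group_names):
        widths = np.concatenate(
            [r.widths for r in report.records if r.year == year and r.widths is not None]
            or [np.empty(0)]
        )
        fig, ax = plt.subplots(figsize=(5, 4))
        if widths.size:
            ax.hist(widths, bins=20, color=_GROUP_COLORS[gi % len(_GROUP_COLORS)])
        ax.set_xlabel("max bundle width [px]")
        ax.set_ylabel("bundles")
        ax.set_title(f"Bundle widths, {year}")
        p = out / f"width_hist_{year}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def _area_histograms(report, out: Path) -> list[Path]:
    paths = []
    for r in report.records:
        if r.histogram is None or r.histogram.counts.size == 0:
            continue
        hist = r.histogram
        fig, ax = plt.subplots(figsize=(5, 4))
        widths = np.diff(hist.bin_edges)
        ax.bar(
            hist.bin_edges[:-1], hist.counts, width=widths, align="edge",
            color="tab:gray", edgecolor="white",
        )
        if r.fit is not None:
            x = np.linspace(0, hist.bin_edges[-1], 400)[1:]
            pdf = stats.genpareto.pdf(x, c=r.fit.shape_k, scale=r.fit.scale_sigma)
            ax.plot(x, pdf * r.n_bundles * widths[0], color="tab:red",
                    label=f"GPD k={r.fit.shape_k:.3f}, σ={r.fit.scale_sigma:.3f}")
            ax.legend()
        ax.set_xlabel("bundle area [px²]")
        ax.set_ylabel("bundles")
        ax.set_title(r.label)
        p = out / f"area_hist_{_slug(r.label)}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def k_sigma_axes(report, ax) -> None:
    """Draw the shape-scale scatter with 95% CI rectangles onto *ax*.

    Each fitted image contributes a point at (k, sigma) and a rectangle
    whose corners are the CI bounds; a vertical line marks the regime
    threshold.
    """
    for gi, year in enumerate(report.group_names):
        color = _GROUP_COLORS[gi % len(_GROUP_COLORS)]
        for r in report.records:
            if r.year != year or r.fit is None:
                continue
            f = r.fit
            ax.add_patch(
                Rectangle(
                    (f.k_ci95[0], f.sigma_ci95[0]),
                    f.k_ci95[1] - f.k_ci95[0],
                    f.sigma_ci95[1] - f.sigma_ci95[0],
                    fill=False,
                    edgecolor=color,
                )
            )
            ax.plot([f.shape_k], [f.scale_sigma], "o", color=color, label=year)
    ax.axvline(report.k_threshold, color="black", linestyle="--", linewidth=1)
    ax.set_xlabel("shape index k")
    ax.set_ylabel("scale σ [px²]")
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    if seen:
        ax.legend(seen.values(), seen.keys())
    ax.autoscale_view()


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in text)


def plot_outputs(report, out_dir) -> list[Path]:
    """Write all figures for a run report; returns the file paths.

    Missing fits are skipped; empty groups produce empty axes rather
    than failing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    paths += _width_histograms(report, out)
    paths += _area_histograms(report, out)

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    k_sigma_axes(report, ax)
    p = out / "k_sigma_scatter.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
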